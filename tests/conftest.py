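import pytest

from postgwas.refdata import Parameters
from postgwas.synthfix import SyntheticScenario, generate_all


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=11, n_loci=3)


@pytest.fixture(scope="session")
def synth(scenario):
    """(bundle, sumstats, truth) for the shared 3-locus scenario."""
    return generate_all(scenario)


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory, scenario):
    from postgwas.synthfix import write_scenario

    outdir = tmp_path_factory.mktemp("scenario")
    return write_scenario(scenario, outdir)
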