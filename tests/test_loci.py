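"""Clumping, candidate collection, and risk-locus merging."""

import numpy as np
import pytest

from postgwas import loci as L
from postgwas.refdata import ConfigError, LdStore, PanelVariant, Parameters, SumstatRecord


def make_snp(snp_id, pos, p, chrom="1"):
    return SumstatRecord(snp_id, chrom, pos, "A", "G", p)


def make_panel(*records, maf=0.3):
    return {r.snp_id: PanelVariant(r.snp_id, r.chrom, r.pos, "G", "A", maf)
            for r in records}


def run_clump(snps, ld_pairs, params=None, panel=None):
    ld = LdStore()
    for a, b, r2 in ld_pairs:
        ld.add(a, b, r2)
    panel = panel if panel is not None else make_panel(*snps)
    return L.select_independent_significant(list(snps), panel, ld, params or Parameters()), ld


# ---------------------------------------------------------------------------
# independent first-principles oracle: dense r2 matrix, greedy from scratch


def oracle_clump(pvals, positions, r2_matrix, threshold):
    """Ascending-p greedy selection against a dense symmetric r2 matrix."""
    order = sorted(range(len(pvals)), key=lambda i: (pvals[i], positions[i], i))
    chosen = []
    for i in order:
        if all(r2_matrix[i][j] < threshold for j in chosen):
            chosen.append(i)
    return chosen


def oracle_lead(chosen, pvals, positions, r2_matrix, threshold):
    order = sorted(chosen, key=lambda i: (pvals[i], positions[i], i))
    leads, members = [], {}
    for i in order:
        home = next((l for l in leads if r2_matrix[i][l] >= threshold), None)
        if home is None:
            leads.append(i)
            members[i] = [i]
        else:
            members[home].append(i)
    return leads, members


class TestSelectIndependentSignificant:
    def test_no_significant_snps_empty(self):
        sel, _ = run_clump([make_snp("a", 100, 0.5)], [])
        assert sel == []

    def test_shadowing_by_stronger_snp(self):
        """A absorbs B (r2 0.7); C is independent of everything selected."""
        snps = [make_snp("A", 100, 1e-10), make_snp("B", 200, 1e-9),
                make_snp("C", 300, 1e-8)]
        sel, _ = run_clump(snps, [("A", "B", 0.7)])
        assert [s.snp.snp_id for s in sel] == ["A", "C"]

    def test_chain_shadowing(self):
        """B is shadowed by A; C stays independent of A although correlated
        with the excluded B."""
        snps = [make_snp("A", 100, 1e-10), make_snp("B", 200, 1e-9),
                make_snp("C", 300, 1e-8)]
        sel, _ = run_clump(snps, [("A", "B", 0.7), ("B", "C", 0.7), ("A", "C", 0.1)])
        assert [s.snp.snp_id for s in sel] == ["A", "C"]

    def test_empty_panel_is_config_error(self):
        with pytest.raises(ConfigError):
            L.select_independent_significant([make_snp("a", 1, 1e-9)], {},
                                             LdStore(), Parameters())

    def test_snps_absent_from_panel_excluded(self):
        snps = [make_snp("A", 100, 1e-10), make_snp("B", 200, 1e-9)]
        panel = make_panel(snps[0])  # B unknown to the panel
        sel, _ = run_clump(snps, [], panel=panel)
        assert [s.snp.snp_id for s in sel] == ["A"]

    def test_monotonic_in_p_sig_and_r2(self):
        rng = np.random.default_rng(5)
        snps = [make_snp(f"s{i}", 100 * i, float(rng.uniform(1e-12, 1e-7)))
                for i in range(10)]
        pairs = [(f"s{i}", f"s{j}", float(rng.uniform(0.05, 1.0)))
                 for i in range(10) for j in range(i + 1, 10) if rng.uniform() < 0.4]
        base, _ = run_clump(snps, pairs)
        stricter, _ = run_clump(snps, pairs, params=Parameters(p_sig=1e-9))
        looser_r2, _ = run_clump(snps, pairs, params=Parameters(r2_ind=0.9))
        assert len(stricter) <= len(base) <= len(looser_r2)


class TestExhaustiveOracle:
    """Implementation matches a from-scratch greedy on random LD matrices."""

    N_MATRICES = 1000

    def test_matches_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1234)
        params = Parameters()
        for _ in range(self.N_MATRICES):
            n = int(rng.integers(2, 13))
            pvals = rng.uniform(1e-14, 4.9e-8, size=n)
            positions = rng.choice(10**6, size=n, replace=False).tolist()
            m = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            vals = np.where(rng.uniform(size=len(iu[0])) < 0.5,
                            rng.uniform(0.05, 1.0, size=len(iu[0])), 0.0)
            m[iu] = vals
            m = m + m.T + np.eye(n)

            snps = [make_snp(f"s{i}", positions[i], float(pvals[i])) for i in range(n)]
            pairs = [(f"s{i}", f"s{j}", float(m[i, j]))
                     for i, j in zip(*iu) if m[i, j] >= 0.05]
            sel, ld = run_clump(snps, pairs, params=params)
            expect = oracle_clump(pvals, positions, m, params.r2_ind)
            assert [s.snp.snp_id for s in sel] == [f"s{i}" for i in expect]

            leads = L.select_lead(sel, ld, params)
            elead, emembers = oracle_lead(expect, pvals, positions, m, params.r2_lead)
            assert [l.snp.snp_id for l in leads] == [f"s{i}" for i in elead]
            for lead, li in zip(leads, elead):
                assert set(lead.member_ind_sig) == {f"s{i}" for i in emembers[li]}

    def test_coverage_property(self):
        """Every excluded significant SNP has r2 >= 0.6 with a selected one."""
        rng = np.random.default_rng(99)
        params = Parameters()
        for _ in range(50):
            n = int(rng.integers(2, 13))
            snps = [make_snp(f"s{i}", 1000 + i, float(rng.uniform(1e-12, 1e-8)))
                    for i in range(n)]
            pairs = [(f"s{i}", f"s{j}", float(rng.uniform(0.05, 1.0)))
                     for i in range(n) for j in range(i + 1, n) if rng.uniform() < 0.5]
            sel, ld = run_clump(snps, pairs, params=params)
            chosen = {s.snp.snp_id for s in sel}
            for s in snps:
                if s.snp_id not in chosen:
                    assert any(ld.r2(s.snp_id, c) >= params.r2_ind for c in chosen)
            leads = L.select_lead(sel, ld, params)
            lead_ids = {l.snp.snp_id for l in leads}
            for s in sel:
                if s.snp.snp_id not in lead_ids:
                    assert any(ld.r2(s.snp.snp_id, c) >= params.r2_lead for c in lead_ids)


class TestSelectLead:
    def test_single_ind_sig_is_its_own_lead(self):
        sel, ld = run_clump([make_snp("A", 100, 1e-10)], [])
        leads = L.select_lead(sel, ld, Parameters())
        assert [l.snp.snp_id for l in leads] == ["A"]

    def test_member_assignment_at_r2_03(self):
        snps = [make_snp("A", 100, 1e-10), make_snp("C", 300, 1e-8)]
        sel, ld = run_clump(snps, [("A", "C", 0.3)])
        leads = L.select_lead(sel, ld, Parameters())
        assert [l.snp.snp_id for l in leads] == ["A"]
        assert set(leads[0].member_ind_sig) == {"A", "C"}

    def test_independent_below_01_both_lead(self):
        snps = [make_snp("A", 100, 1e-10), make_snp("C", 300, 1e-8)]
        sel, ld = run_clump(snps, [("A", "C", 0.05)])
        leads = L.select_lead(sel, ld, Parameters())
        assert [l.snp.snp_id for l in leads] == ["A", "C"]


class TestCollectCandidates:
    def _setup(self):
        ind = make_snp("A", 1000, 1e-10)
        panel = {
            "A": PanelVariant("A", "1", 1000, "G", "A", 0.3),
            "proxy": PanelVariant("proxy", "1", 1500, "C", "T", 0.2),
            "rare": PanelVariant("rare", "1", 1600, "C", "T", 0.005),
            "far": PanelVariant("far", "1", 9000, "C", "T", 0.3),
        }
        ld = LdStore()
        ld.add("A", "proxy", 0.65)
        ld.add("A", "rare", 0.65)
        ld.add("A", "far", 0.2)
        sel = L.select_independent_significant([ind], panel, ld, Parameters())
        return sel, panel, ld, [ind]

    def test_proxy_without_gwas_p_included_and_flagged(self):
        sel, panel, ld, ss = self._setup()
        cands = L.collect_candidates(sel, panel, ld, ss, Parameters())
        by_id = {c.variant.snp_id: c for c in cands}
        assert by_id["proxy"].p is None and not by_id["proxy"].gwas_tagged
        assert by_id["proxy"].best_r2 == 0.65

    def test_low_maf_candidate_excluded(self):
        sel, panel, ld, ss = self._setup()
        cands = L.collect_candidates(sel, panel, ld, ss, Parameters())
        ids = {c.variant.snp_id for c in cands}
        assert "rare" not in ids and "far" not in ids

    def test_ind_sig_is_its_own_candidate_with_r2_one(self):
        sel, panel, ld, ss = self._setup()
        cands = L.collect_candidates(sel, panel, ld, ss, Parameters())
        me = next(c for c in cands if c.variant.snp_id == "A")
        assert me.best_r2 == 1.0 and me.nearest_ind_sig == "A"

    def test_maf_filter_never_removes_ind_sig(self):
        ind = make_snp("A", 1000, 1e-10)
        panel = {"A": PanelVariant("A", "1", 1000, "G", "A", 0.001)}
        sel = L.select_independent_significant([ind], panel, LdStore(), Parameters())
        cands = L.collect_candidates(sel, panel, LdStore(), [ind], Parameters())
        assert [c.variant.snp_id for c in cands] == ["A"]


class TestDefineLoci:
    def _loci_for_gap(self, gap_bp):
        """Two single-SNP blocks whose block edges are gap_bp apart."""
        a = make_snp("A", 1_000_000, 1e-10)
        b = make_snp("B", 1_000_000 + gap_bp, 1e-9)
        panel = make_panel(a, b)
        ld = LdStore()
        sel = L.select_independent_significant([a, b], panel, ld, Parameters())
        leads = L.select_lead(sel, ld, Parameters())
        cands = L.collect_candidates(sel, panel, ld, [a, b], Parameters())
        return L.define_loci(sel, cands, leads, ld, Parameters())

    def test_gap_below_250kb_merges(self):
        assert len(self._loci_for_gap(150_000)) == 1

    def test_gap_at_exactly_250kb_does_not_merge(self):
        assert len(self._loci_for_gap(250_000)) == 2
        assert len(self._loci_for_gap(249_999)) == 1

    def test_gap_above_250kb_two_loci(self):
        loci = self._loci_for_gap(300_000)
        assert len(loci) == 2
        assert [l.locus_id for l in loci] == [1, 2]

    def test_span_covers_candidates(self):
        ind = make_snp("A", 1_100_000, 1e-10)
        panel = {
            "A": PanelVariant("A", "1", 1_100_000, "G", "A", 0.3),
            "L": PanelVariant("L", "1", 1_000_000, "C", "T", 0.3),
            "R": PanelVariant("R", "1", 1_200_000, "C", "T", 0.3),
        }
        ld = LdStore()
        ld.add("A", "L", 0.8)
        ld.add("A", "R", 0.7)
        sel = L.select_independent_significant([ind], panel, ld, Parameters())
        leads = L.select_lead(sel, ld, Parameters())
        cands = L.collect_candidates(sel, panel, ld, [ind], Parameters())
        (locus,) = L.define_loci(sel, cands, leads, ld, Parameters())
        assert (locus.start, locus.end) == (1_000_000, 1_200_000)
        assert locus.top_snp.snp_id == "A"

    def test_candidates_partitioned_across_loci(self, synth, params):
        bundle, sumstats, _ = synth
        ind, leads, cands, loci = L.characterize(sumstats, bundle.panel, bundle.ld, params)
        assigned = [c.variant.snp_id for l in loci for c in l.candidates]
        assert sorted(assigned) == sorted(c.variant.snp_id for c in cands)
        for l1, l2 in zip(loci, loci[1:]):
            if l1.chrom == l2.chrom:
                assert l2.start - l1.end >= 250_000


class TestPredefined:
    def test_predefined_equal_to_top_snp_is_idempotent(self, synth, params):
        bundle, sumstats, truth = synth
        default = L.characterize(sumstats, bundle.panel, bundle.ld, params)
        forced = L.characterize(sumstats, bundle.panel, bundle.ld, params,
                                predefined_leads=[truth.causal_snps[0]])
        assert [i.snp.snp_id for i in default[0]] == [i.snp.snp_id for i in forced[0]]
        assert len(default[3]) == len(forced[3])

    def test_region_without_significant_snp_gives_zero_loci(self, synth, params):
        bundle, sumstats, _ = synth
        out = L.characterize(sumstats, bundle.panel, bundle.ld, params,
                             regions=[("1", 1, 100)])
        assert out == ([], [], [], [])

    def test_nonsignificant_predefined_lead_still_forced(self):
        a = make_snp("A", 1000, 0.5)
        panel = make_panel(a)
        sel, leads, cands, loci = L.characterize([a], panel, LdStore(), Parameters(),
                                                 predefined_leads=["A"])
        assert sel[0].forced and leads[0].snp.snp_id == "A"
        assert len(loci) == 1

    def test_predefined_lead_missing_from_panel_is_error(self):
        a = make_snp("A", 1000, 1e-9)
        with pytest.raises(ConfigError, match="nosuch"):
            L.characterize([a], make_panel(a), LdStore(), Parameters(),
                           predefined_leads=["nosuch"])
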