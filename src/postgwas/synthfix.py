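"""Seeded synthetic fixtures with planted structure.

Every input table the pipeline consumes can be generated at desk scale from a
single integer seed: association blocks with a linearly decaying LD profile
and one planted causal SNP each, genes playing planted roles per locus (a
coding target carrying a deleterious exonic SNP, a distal cis-eQTL target,
a distal chromatin-interaction target, plus evidence-free distractors), an
expression matrix with planted tissue shifts, and gene-set collections that
contain the planted groups among random distractor sets.

The LD model is deliberately simple — r2 = max(0, 0.95 - d * rate) within a
block, exactly 0 across blocks — which makes the expected clumping answer
computable by construction. It is not a population-genetic simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import refdata
from .refdata import (
    CatalogEntry,
    ConfigError,
    EpigenomeRegionSet,
    EqtlRecord,
    ExpressionMatrix,
    GeneModel,
    GeneSetCollection,
    InteractionRecord,
    LdStore,
    PanelVariant,
    ReferenceBundle,
    ScoreTables,
    SumstatRecord,
)

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic data set."""

    seed: int
    n_loci: int = 3
    snps_per_block: int = 21          # odd, so the causal SNP sits at the center
    snp_step_bp: int = 2_000          # spacing of block SNPs
    block_spacing_bp: int = 2_000_000  # causal-to-causal distance (>= 1 Mb of r2 = 0)
    r2_decay_per_bp: float = 0.95 / 50_000.0  # r2 = max(0, 0.95 - d * rate)
    planted_log10p: float = 12.0      # causal SNP p = 10**-planted_log10p
    n_null_snps: int = 100            # unlinked background SNPs with null p-values
    n_distractor_genes: int = 8       # evidence-free genes per locus
    n_tissues: int = 4
    samples_per_tissue: int = 10
    planted_lfc: float = 2.0          # log2 shift of planted DEG genes in their tissue
    omit_fraction: float = 0.0        # block SNPs hidden from the GWAS input
    n_distractor_sets: int = 5        # random GMT sets beside the planted ones
    chrom: str = "1"
    chrom_length: int = 250_000_000
    eqtl_offset_bp: int = 300_000     # distance of the eQTL target gene from the block
    ci_offset_bp: int = 600_000       # distance of the interaction target gene

    def __post_init__(self) -> None:
        if self.snps_per_block % 2 == 0:
            raise ConfigError("snps_per_block must be odd")
        block_span = (self.snps_per_block - 1) * self.snp_step_bp
        if self.block_spacing_bp - block_span < 1_000_000:
            raise ConfigError("blocks must be separated by >= 1 Mb of zero LD")
        last = self.first_causal_pos + (self.n_loci - 1) * self.block_spacing_bp
        if last + self.ci_offset_bp + 200_000 > self.chrom_length:
            raise ConfigError("blocks overflow the chromosome length")

    @property
    def first_causal_pos(self) -> int:
        return 1_000_000

    def causal_pos(self, locus: int) -> int:
        return self.first_causal_pos + locus * self.block_spacing_bp

    def block_positions(self, locus: int) -> list[int]:
        half = self.snps_per_block // 2
        c = self.causal_pos(locus)
        return [c + (j - half) * self.snp_step_bp for j in range(self.snps_per_block)]


@dataclass
class PlantedTruth:
    """Machine-readable manifest of what was planted (for test assertions)."""

    causal_snps: list[str] = field(default_factory=list)
    coding_targets: list[str] = field(default_factory=list)
    eqtl_targets: list[str] = field(default_factory=list)
    ci_targets: list[str] = field(default_factory=list)
    deg_genes: dict[str, str] = field(default_factory=dict)      # gene -> tissue
    planted_set_names: list[str] = field(default_factory=list)
    tissues: list[str] = field(default_factory=list)
    eqtl_tissue: str = ""
    ci_tissue: str = ""
    omitted_snps: list[str] = field(default_factory=list)


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return NUCLEOTIDES[ref], NUCLEOTIDES[alt]


def _make_gene(gene_id: str, symbol: str, chrom: str, start: int, strand: str,
               gene_type: str = "protein_coding", n_exons: int = 3,
               exon_len: int = 300, intron_len: int = 700) -> GeneModel:
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    end = exons[-1][1]
    return GeneModel(gene_id=gene_id, symbol=symbol, gene_type=gene_type,
                     chrom=chrom, start=start, end=end, strand=strand,
                     exons=tuple(exons))


def generate_reference(scenario: SyntheticScenario) -> tuple[ReferenceBundle, PlantedTruth]:
    """Panel + LD + genes + scores + eQTLs + interactions + regions + catalog."""
    rng = np.random.default_rng(scenario.seed)
    truth = PlantedTruth()
    bundle = ReferenceBundle()
    chrom = scenario.chrom
    tissues = [f"tissue_{i}" for i in range(scenario.n_tissues)]
    truth.tissues = tissues
    truth.eqtl_tissue = tissues[0]
    truth.ci_tissue = tissues[min(1, len(tissues) - 1)]

    for locus in range(scenario.n_loci):
        positions = scenario.block_positions(locus)
        causal_pos = scenario.causal_pos(locus)
        block_ids = []
        for j, pos in enumerate(positions):
            sid = f"rs{locus + 1}_{j:02d}"
            ref, alt = _alleles(rng)
            maf = float(rng.uniform(0.05, 0.5))
            bundle.panel[sid] = PanelVariant(sid, chrom, pos, ref, alt, maf)
            block_ids.append(sid)
            if pos == causal_pos:
                truth.causal_snps.append(sid)
        # linear r2 decay; pairs below the 0.05 storage floor stay absent
        for a in range(len(block_ids)):
            for b in range(a + 1, len(block_ids)):
                d = abs(positions[a] - positions[b])
                r2 = max(0.0, 0.95 - d * scenario.r2_decay_per_bp)
                if r2 >= 0.05 and d <= 1_000_000:
                    bundle.ld.add(block_ids[a], block_ids[b], round(r2, 6))

        # planted genes -------------------------------------------------
        coding_id = f"GENE_L{locus + 1}_CODING"
        # place the gene so that the causal SNP falls inside its first exon
        coding = _make_gene(coding_id, f"CD{locus + 1}", chrom, causal_pos - 100, "+")
        bundle.genes.append(coding)
        truth.coding_targets.append(coding_id)
        causal = bundle.panel[truth.causal_snps[-1]]
        bundle.scores.cadd[(chrom, causal.pos, causal.ref_allele, causal.alt_allele)] = \
            float(rng.uniform(15.0, 30.0))
        # deleterious-looking scores for the causal SNP only; neighbors stay low
        for sid in block_ids:
            v = bundle.panel[sid]
            if sid != truth.causal_snps[-1] and rng.uniform() < 0.5:
                bundle.scores.cadd[(chrom, v.pos, v.ref_allele, v.alt_allele)] = \
                    float(rng.uniform(0.1, 5.0))
        bundle.scores.regulomedb[(chrom, causal.pos)] = "1a"
        bundle.scores.chromhmm[(chrom, (causal.pos - 1) // refdata.CHROMHMM_BIN, "E001")] = 1

        eqtl_id = f"GENE_L{locus + 1}_EQTL"
        eqtl_start = causal_pos + scenario.eqtl_offset_bp
        eqtl_gene = _make_gene(eqtl_id, f"EQ{locus + 1}", chrom, eqtl_start, "+")
        bundle.genes.append(eqtl_gene)
        truth.eqtl_targets.append(eqtl_id)
        # the eQTL is carried by a non-causal candidate SNP of the block
        carrier = bundle.panel[block_ids[scenario.snps_per_block // 2 + 1]]
        bundle.eqtls.append(EqtlRecord(chrom, carrier.pos, carrier.alt_allele,
                                       carrier.ref_allele, eqtl_id,
                                       truth.eqtl_tissue,
                                       p=float(rng.uniform(1e-10, 1e-6)),
                                       fdr=float(rng.uniform(1e-6, 0.01))))
        # a non-qualifying eQTL (FDR above threshold) for a distractor check
        bundle.eqtls.append(EqtlRecord(chrom, carrier.pos, carrier.alt_allele,
                                       carrier.ref_allele,
                                       f"GENE_L{locus + 1}_DIS0",
                                       truth.eqtl_tissue,
                                       p=float(rng.uniform(0.001, 0.01)),
                                       fdr=float(rng.uniform(0.2, 0.9))))

        ci_id = f"GENE_L{locus + 1}_CI"
        ci_strand = "+" if locus % 2 == 0 else "-"
        ci_start = causal_pos + scenario.ci_offset_bp
        ci_gene = _make_gene(ci_id, f"CI{locus + 1}", chrom, ci_start, ci_strand)
        bundle.genes.append(ci_gene)
        truth.ci_targets.append(ci_id)
        # one end covers the block center, the other covers the gene promoter
        block_lo, block_hi = positions[0], positions[-1]
        tss = ci_gene.tss
        bundle.interactions.append(InteractionRecord(
            chrom, block_lo - 500, block_hi + 500,
            chrom, tss - 2_000, tss + 2_000,
            truth.ci_tissue, fdr=float(rng.uniform(1e-12, 1e-8))))
        # a non-significant interaction that must be ignored
        bundle.interactions.append(InteractionRecord(
            chrom, block_lo - 500, block_hi + 500,
            chrom, tss + 50_000, tss + 54_000,
            truth.ci_tissue, fdr=1e-3))
        # enhancer region over the block (so enhancer filtering keeps the SNPs)
        if not bundle.regions:
            bundle.regions.append(EpigenomeRegionSet("enhancer", "E001"))
            bundle.regions.append(EpigenomeRegionSet("promoter", "E001"))
        bundle.regions[0].intervals.append((chrom, block_lo - 500, block_hi + 500))
        bundle.regions[1].intervals.append((chrom, tss - 2_000, tss + 2_000))

        for d in range(scenario.n_distractor_genes):
            dis_id = f"GENE_L{locus + 1}_DIS{d}"
            dis_start = causal_pos - 400_000 - d * 50_000
            bundle.genes.append(_make_gene(dis_id, f"DS{locus + 1}_{d}", chrom,
                                           dis_start, "+" if d % 2 == 0 else "-"))

        # a catalog entry sitting exactly on the causal SNP
        bundle.catalog.append(CatalogEntry(chrom, causal_pos,
                                           trait=f"trait_{locus + 1}",
                                           reported_p=10.0 ** -scenario.planted_log10p))

    # unlinked null SNPs far from every block
    null_base = scenario.causal_pos(scenario.n_loci - 1) + scenario.block_spacing_bp + 2_000_000
    for j in range(scenario.n_null_snps):
        sid = f"rsNULL_{j:03d}"
        ref, alt = _alleles(rng)
        bundle.panel[sid] = PanelVariant(sid, chrom, null_base + j * 5_000, ref, alt,
                                         float(rng.uniform(0.05, 0.5)))

    # gene-level intolerance scores
    for g in bundle.genes:
        bundle.pli[g.gene_id] = float(rng.uniform(0.0, 1.0))
        bundle.ncrvis[g.gene_id] = float(rng.normal(0.0, 1.0))

    bundle.genes.sort(key=lambda g: (g.start, g.gene_id))
    return bundle, truth


def generate_sumstats(
    scenario: SyntheticScenario,
    bundle: ReferenceBundle,
    truth: PlantedTruth,
) -> list[SumstatRecord]:
    """Planted causal SNPs get the planted p; block neighbors interpolate
    toward the null as -log10 p scaled by their r2 with the causal SNP; null
    SNPs draw Uniform(0,1). A fraction of non-causal block SNPs is omitted to
    exercise non-GWAS-tagged proxies."""
    rng = np.random.default_rng(scenario.seed + 1)
    records: list[SumstatRecord] = []
    causal_set = set(truth.causal_snps)
    truth.omitted_snps = []
    for sid, v in sorted(bundle.panel.items(), key=lambda kv: kv[1].pos):
        if sid in causal_set:
            p = 10.0 ** -scenario.planted_log10p
        elif sid.startswith("rsNULL"):
            p = float(rng.uniform(0.0, 1.0))
            p = max(p, 1e-6)  # a null draw landing below 5e-8 would be a spurious plant
        else:
            locus = int(sid[2:].split("_")[0]) - 1
            causal_id = truth.causal_snps[locus]
            r2 = bundle.ld.r2(sid, causal_id)
            logp = scenario.planted_log10p * r2 * float(rng.uniform(0.85, 1.0))
            p = min(10.0 ** -logp, 1.0)
            if rng.uniform() < scenario.omit_fraction:
                truth.omitted_snps.append(sid)
                continue
        records.append(SumstatRecord(sid, v.chrom, v.pos, v.alt_allele, v.ref_allele,
                                     p=max(p, 5e-324)))
    return records


def generate_expression(
    scenario: SyntheticScenario,
    bundle: ReferenceBundle,
    truth: PlantedTruth,
) -> tuple[ExpressionMatrix, list[GeneSetCollection]]:
    """Baseline log2 expression i.i.d. Normal(2, 0.5) per sample; each planted
    DEG gene (the coding target of locus i) is shifted by the planted lfc in
    tissue i mod n_tissues. RPKM = max(2^x - 1, 0)."""
    rng = np.random.default_rng(scenario.seed + 2)
    genes = [g.gene_id for g in bundle.genes]
    tissues = truth.tissues
    samples, tissue_of = [], {}
    for t in tissues:
        for j in range(scenario.samples_per_tissue):
            s = f"{t}_s{j:02d}"
            samples.append(s)
            tissue_of[s] = t

    logx = rng.normal(2.0, 0.5, size=(len(genes), len(samples)))
    truth.deg_genes = {}
    for locus, gene_id in enumerate(truth.coding_targets):
        tissue = tissues[locus % len(tissues)]
        gi = genes.index(gene_id)
        cols = [i for i, s in enumerate(samples) if tissue_of[s] == tissue]
        logx[gi, cols] += scenario.planted_lfc
        truth.deg_genes[gene_id] = tissue
    rpkm = np.maximum(np.exp2(logx) - 1.0, 0.0)
    expr = ExpressionMatrix(genes, samples, rpkm, tissue_of)

    planted = GeneSetCollection(source_label="planted")
    planted.sets["planted_eqtl_targets"] = frozenset(truth.eqtl_targets)
    planted.sets["planted_ci_targets"] = frozenset(truth.ci_targets)
    planted.sets["planted_coding_targets"] = frozenset(truth.coding_targets)
    truth.planted_set_names = sorted(planted.sets)
    distract = GeneSetCollection(source_label="distractor")
    pool = list(genes)
    for j in range(scenario.n_distractor_sets):
        size = int(rng.integers(3, max(4, len(pool) // 2)))
        members = rng.choice(pool, size=min(size, len(pool)), replace=False)
        distract.sets[f"random_set_{j}"] = frozenset(str(m) for m in members)
    return expr, [planted, distract]


def generate_all(scenario: SyntheticScenario):
    """Convenience: reference bundle + sumstats + expression + gene sets + truth."""
    bundle, truth = generate_reference(scenario)
    sumstats = generate_sumstats(scenario, bundle, truth)
    expr, collections = generate_expression(scenario, bundle, truth)
    bundle.expression = expr
    bundle.gene_sets = collections
    return bundle, sumstats, truth


def write_scenario(scenario: SyntheticScenario, outdir) -> dict[str, str]:
    """Write a complete input directory plus a manifest of the planted truth.

    Returns the path map (logical name -> file path). Byte-identical for a
    fixed scenario.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle, sumstats, truth = generate_all(scenario)

    paths = {
        "sumstats": outdir / "sumstats.tsv",
        "panel": outdir / "panel.tsv",
        "ld": outdir / "ld.tsv",
        "genes": outdir / "genes.tsv",
        "cadd": outdir / "cadd.tsv",
        "regulomedb": outdir / "regulomedb.tsv",
        "chromhmm": outdir / "chromhmm.tsv",
        "eqtls": outdir / "eqtls.tsv",
        "interactions": outdir / "interactions.bedpe",
        "enhancers": outdir / "enhancers.E001.bed",
        "promoters": outdir / "promoters.E001.bed",
        "expression": outdir / "expression.tsv",
        "tissue_map": outdir / "tissue_map.tsv",
        "gmt_planted": outdir / "planted.gmt",
        "gmt_distractor": outdir / "distractor.gmt",
        "catalog": outdir / "catalog.tsv",
        "pli": outdir / "pli.tsv",
        "ncrvis": outdir / "ncrvis.tsv",
        "manifest": outdir / "manifest.json",
    }
    refdata.write_sumstats(paths["sumstats"], sumstats)
    refdata.write_panel(paths["panel"], bundle.panel)
    refdata.write_ld(paths["ld"], bundle.ld)
    refdata.write_gene_models(paths["genes"], bundle.genes)
    refdata.write_score_tables(bundle.scores, cadd_path=paths["cadd"],
                               rdb_path=paths["regulomedb"],
                               chromhmm_path=paths["chromhmm"])
    refdata.write_eqtls(paths["eqtls"], bundle.eqtls)
    refdata.write_interactions(paths["interactions"], bundle.interactions)
    refdata.write_regions(paths["enhancers"], bundle.regions[0])
    refdata.write_regions(paths["promoters"], bundle.regions[1])
    refdata.write_expression(paths["expression"], paths["tissue_map"], bundle.expression)
    refdata.write_gmt(paths["gmt_planted"], bundle.gene_sets[0])
    refdata.write_gmt(paths["gmt_distractor"], bundle.gene_sets[1])
    refdata.write_catalog(paths["catalog"], bundle.catalog)
    refdata.write_score_map(paths["pli"], bundle.pli, "pLI")
    refdata.write_score_map(paths["ncrvis"], bundle.ncrvis, "ncRVIS")
    with open(paths["manifest"], "w") as fh:
        json.dump({"scenario": asdict(scenario), "truth": asdict(truth)}, fh,
                  indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
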