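"""SNP-to-gene mapping: positional, cis-eQTL, and chromatin-interaction
strategies, each with its own functional SNP filter, combined into one
prioritized gene table.

The per-strategy filters act on copies of the ORIGINAL candidate set — a CADD
filter chosen for positional mapping never alters the SNPs available to eQTL
or chromatin-interaction mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .refdata import (
    ConfigError,
    EpigenomeRegionSet,
    EqtlRecord,
    GeneModel,
    InteractionRecord,
    RDB_RANK,
)
from .loci import RiskLocus
from .snpannot import AnnotatedSNP, GeneIndex

log = logging.getLogger(__name__)

CIS_WINDOW_BP = 1_000_000  # cis-eQTL distance bound


@dataclass
class MappingEvidence:
    strategy: str                      # positional | eqtl | chromatin
    gene_id: str
    snp_ids: set[str] = field(default_factory=set)
    detail: dict = field(default_factory=dict)


def filter_snps_functional(
    annotated: list[AnnotatedSNP],
    cadd_min: float | None = None,
    rdb_max: str | None = None,
    allowed_states: set[int] | None = None,
    allowed_consequences: set[str] | None = None,
) -> list[AnnotatedSNP]:
    """Conjunction of the provided functional filters; a SNP lacking a score
    required by an active filter fails that filter. With no filters this is
    the identity."""
    if rdb_max is not None and rdb_max not in RDB_RANK:
        raise ConfigError(f"unknown RegulomeDB category {rdb_max!r}")
    out = []
    for a in annotated:
        if cadd_min is not None and (a.cadd is None or a.cadd < cadd_min):
            continue
        if rdb_max is not None and (a.rdb is None or RDB_RANK[a.rdb] > RDB_RANK[rdb_max]):
            continue
        if allowed_states is not None:
            if not a.chromhmm_states or not any(
                    s in allowed_states for s in a.chromhmm_states.values()):
                continue
        if allowed_consequences is not None and a.consequence not in allowed_consequences:
            continue
        out.append(a)
    if not out and annotated:
        log.warning("functional SNP filter left an empty set")
    return out


def positional_map(
    filtered: list[AnnotatedSNP],
    genes: list[GeneModel] | GeneIndex,
    window_kb: float | None = 10.0,
    allowed_consequences: set[str] | None = None,
) -> dict[str, MappingEvidence]:
    """Window mode (``window_kb`` set): a SNP maps to every gene whose span,
    padded by the window, contains it. Consequence mode (``allowed_consequences``
    set): a SNP maps to its annotated gene(s) iff its consequence is selected."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    evidence: dict[str, MappingEvidence] = {}

    def add(gene_id: str, a: AnnotatedSNP, distance: int) -> None:
        ev = evidence.setdefault(gene_id, MappingEvidence("positional", gene_id))
        ev.snp_ids.add(a.snp_id)
        det = ev.detail.setdefault("snps", {})
        det[a.snp_id] = {"consequence": a.consequence, "distance": distance}

    if allowed_consequences is not None:
        for a in filtered:
            if a.consequence in allowed_consequences:
                for gene_id, dist in a.annotated_genes:
                    if gene_id in index.by_id:
                        add(gene_id, a, dist)
        return evidence

    if window_kb is None:
        raise ConfigError("positional_map needs window_kb or allowed_consequences")
    pad = int(window_kb * 1000)
    for a in filtered:
        v = a.candidate.variant
        for g in index.overlapping(v.chrom, v.pos, pad=pad):
            d = 0 if g.start <= v.pos <= g.end else min(abs(v.pos - g.start), abs(v.pos - g.end))
            add(g.gene_id, a, d)
    return evidence


def eqtl_map(
    filtered: list[AnnotatedSNP],
    eqtls: list[EqtlRecord],
    genes: list[GeneModel] | GeneIndex,
    tissues: list[str],
    fdr_max: float | None = 0.05,
    p_max: float | None = None,
) -> dict[str, MappingEvidence]:
    """Join candidate SNPs to significant cis-eQTL records in the selected
    tissues: match on (chrom, pos) with exact or allele-swapped orientation,
    keep records with source FDR <= ``fdr_max`` (or nominal p <= ``p_max`` when
    nominal filtering is chosen), and enforce the 1 Mb cis bound against the
    gene body."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    available = {q.tissue for q in eqtls}
    for t in tissues:
        if t not in available:
            raise ConfigError(f"requested eQTL tissue {t!r} absent from the eQTL store")
    tissue_set = set(tissues)

    by_pos: dict[tuple[str, int], list[EqtlRecord]] = {}
    for q in eqtls:
        if q.tissue in tissue_set:
            by_pos.setdefault((q.chrom, q.pos), []).append(q)

    evidence: dict[str, MappingEvidence] = {}
    for a in filtered:
        v = a.candidate.variant
        for q in by_pos.get((v.chrom, v.pos), []):
            alleles_ok = (
                (q.effect_allele, q.other_allele) in (
                    (v.alt_allele, v.ref_allele), (v.ref_allele, v.alt_allele))
            )
            if not alleles_ok:
                continue
            if p_max is not None:
                if q.p > p_max:
                    continue
            elif fdr_max is not None and q.fdr > fdr_max:
                continue
            g = index.by_id.get(q.gene_id)
            if g is None or g.chrom != v.chrom:
                continue
            dist = 0 if g.start <= v.pos <= g.end else min(abs(v.pos - g.start), abs(v.pos - g.end))
            if dist > CIS_WINDOW_BP:
                continue
            ev = evidence.setdefault(q.gene_id, MappingEvidence("eqtl", q.gene_id))
            ev.snp_ids.add(v.snp_id)
            ev.detail.setdefault("tissues", set()).add(q.tissue)
            ev.detail["min_fdr"] = min(ev.detail.get("min_fdr", 1.0), q.fdr)
            ev.detail["min_p"] = min(ev.detail.get("min_p", 1.0), q.p)
    return evidence


def _overlaps(start: int, end: int, lo: int, hi: int) -> bool:
    return start <= hi and lo <= end  # closed intervals, >=1 shared base


def chromatin_map(
    filtered: list[AnnotatedSNP],
    interactions: list[InteractionRecord],
    genes: list[GeneModel] | GeneIndex,
    tissues: list[str],
    ci_fdr_max: float = 1e-6,
    promoter_up: int = 250,
    promoter_down: int = 500,
    enhancer_sets: list[EpigenomeRegionSet] | None = None,
    promoter_sets: list[EpigenomeRegionSet] | None = None,
) -> dict[str, MappingEvidence]:
    """A SNP overlapping one end of a significant interaction maps every gene
    whose strand-aware promoter window overlaps the other end. Both
    orientations are tested; interactions where the SNP end also overlaps the
    gene's promoter are kept and flagged ``promoter_promoter``. Optional
    epigenome filters: the SNP end must fall in a predicted enhancer, and/or
    the gene promoter must overlap a predicted promoter region."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    tissue_set = set(tissues)
    kept = [r for r in interactions if r.tissue in tissue_set and r.fdr <= ci_fdr_max]

    # promoter windows indexed per chromosome
    prom_tree: dict[str, IntervalTree] = {}
    prom_of: dict[str, tuple[int, int]] = {}
    for g in index.genes:
        lo, hi = g.promoter(up=promoter_up, down=promoter_down)
        prom_of[g.gene_id] = (lo, hi)
        prom_tree.setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1, g)

    def snp_in_enhancer(chrom: str, pos: int) -> bool:
        if not enhancer_sets:
            return True
        return any(rs.contains(chrom, pos) for rs in enhancer_sets if rs.kind == "enhancer")

    def promoter_predicted(g: GeneModel) -> bool:
        if not promoter_sets:
            return True
        lo, hi = prom_of[g.gene_id]
        return any(rs.overlaps(g.chrom, lo, hi) for rs in promoter_sets if rs.kind == "promoter")

    evidence: dict[str, MappingEvidence] = {}
    for rec in kept:
        ends = (
            ((rec.chrom_a, rec.start_a, rec.end_a), (rec.chrom_b, rec.start_b, rec.end_b)),
            ((rec.chrom_b, rec.start_b, rec.end_b), (rec.chrom_a, rec.start_a, rec.end_a)),
        )
        for (sc, ss, se), (gc, gs, ge) in ends:
            snps_here = [
                a for a in filtered
                if a.candidate.variant.chrom == sc and ss <= a.candidate.variant.pos <= se
                and snp_in_enhancer(sc, a.candidate.variant.pos)
            ]
            if not snps_here:
                continue
            tree = prom_tree.get(gc)
            if tree is None:
                continue
            for iv in tree.overlap(gs, ge + 1):
                g: GeneModel = iv.data
                if not promoter_predicted(g):
                    continue
                lo, hi = prom_of[g.gene_id]
                promoter_promoter = g.chrom == sc and _overlaps(lo, hi, ss, se)
                ev = evidence.setdefault(g.gene_id, MappingEvidence("chromatin", g.gene_id))
                ev.snp_ids.update(a.snp_id for a in snps_here)
                ev.detail.setdefault("tissues", set()).add(rec.tissue)
                ev.detail.setdefault("regions", []).append(
                    ((sc, ss, se), (gc, gs, ge)))
                ev.detail["min_fdr"] = min(ev.detail.get("min_fdr", 1.0), rec.fdr)
                if promoter_promoter:
                    ev.detail["promoter_promoter"] = True
    return evidence


@dataclass
class MappedGene:
    gene_id: str
    symbol: str
    strategies: dict[str, MappingEvidence]
    loci: set[int]
    inside_locus: bool
    pli: float | None = None
    ncrvis: float | None = None


def combine_maps(
    positional: dict[str, MappingEvidence] | None,
    eqtl: dict[str, MappingEvidence] | None,
    chromatin: dict[str, MappingEvidence] | None,
    loci: list[RiskLocus],
    genes: list[GeneModel] | GeneIndex,
    pli: dict[str, float] | None = None,
    ncrvis: dict[str, float] | None = None,
    gene_types: set[str] | None = frozenset({"protein_coding"}),
) -> list[MappedGene]:
    """Union of the three strategies into one gene table (set union, so the
    result is independent of strategy order). Locus attribution goes through
    each supporting SNP's locus; ``inside_locus`` records whether the gene
    span overlaps any supporting locus span."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    locus_of_snp: dict[str, int] = {}
    locus_by_id = {l.locus_id: l for l in loci}
    for locus in loci:
        for c in locus.candidates:
            locus_of_snp[c.variant.snp_id] = locus.locus_id

    merged: dict[str, dict[str, MappingEvidence]] = {}
    for evmap in (positional, eqtl, chromatin):
        for gene_id, ev in (evmap or {}).items():
            merged.setdefault(gene_id, {})[ev.strategy] = ev

    out: list[MappedGene] = []
    for gene_id in sorted(merged):
        g = index.by_id.get(gene_id)
        if g is None:
            log.warning("mapped gene %s absent from gene models; dropped", gene_id)
            continue
        if gene_types is not None and g.gene_type not in gene_types:
            continue
        strategies = merged[gene_id]
        gene_loci = {
            locus_of_snp[sid]
            for ev in strategies.values() for sid in ev.snp_ids
            if sid in locus_of_snp
        }
        inside = any(
            locus_by_id[lid].chrom == g.chrom
            and _overlaps(g.start, g.end, locus_by_id[lid].start, locus_by_id[lid].end)
            for lid in gene_loci
        )
        out.append(MappedGene(
            gene_id=gene_id, symbol=g.symbol, strategies=strategies,
            loci=gene_loci, inside_locus=inside,
            pli=(pli or {}).get(gene_id), ncrvis=(ncrvis or {}).get(gene_id),
        ))
    return out


def gene_table(mapped: list[MappedGene]) -> pd.DataFrame:
    """Flat per-gene table (the ``genes.txt`` payload)."""
    rows = []
    for m in mapped:
        pos_ev = m.strategies.get("positional")
        eq_ev = m.strategies.get("eqtl")
        ci_ev = m.strategies.get("chromatin")
        rows.append({
            "gene_id": m.gene_id,
            "symbol": m.symbol,
            "pos_map": pos_ev is not None,
            "eqtl_map": eq_ev is not None,
            "ci_map": ci_ev is not None,
            "n_pos_snps": len(pos_ev.snp_ids) if pos_ev else 0,
            "n_eqtl_snps": len(eq_ev.snp_ids) if eq_ev else 0,
            "n_ci_snps": len(ci_ev.snp_ids) if ci_ev else 0,
            "eqtl_min_fdr": eq_ev.detail.get("min_fdr") if eq_ev else None,
            "ci_min_fdr": ci_ev.detail.get("min_fdr") if ci_ev else None,
            "loci": ";".join(str(x) for x in sorted(m.loci)),
            "inside_locus": m.inside_locus,
            "pLI": m.pli,
            "ncRVIS": m.ncrvis,
        })
    return pd.DataFrame(rows, columns=[
        "gene_id", "symbol", "pos_map", "eqtl_map", "ci_map",
        "n_pos_snps", "n_eqtl_snps", "n_ci_snps", "eqtl_min_fdr", "ci_min_fdr",
        "loci", "inside_locus", "pLI", "ncRVIS",
    ])


def genes_per_locus(mapped: list[MappedGene], loci: list[RiskLocus]) -> dict[int, int]:
    """Mapped-gene count per locus (supports the single-gene-locus summary)."""
    counts = {l.locus_id: 0 for l in loci}
    for m in mapped:
        for lid in m.loci:
            counts[lid] += 1
    return counts
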