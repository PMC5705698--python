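"""Functional annotation of candidate SNPs.

A positional consequence classifier (a simplified gene-based annotator over
the loaded gene models), plus left-joins against the CADD / RegulomeDB /
chromatin-state tables and exact positional matching against a catalog of
previously reported SNP-trait associations.

The classifier deliberately stops at the positional level: exonic sub-classes
that need codon logic (nonsynonymous, stopgain) are out of scope, and a
user-supplied per-variant consequence table can override the classifier for
variants with externally computed consequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .refdata import CatalogEntry, GeneModel, ScoreTables
from .loci import CandidateSNP

log = logging.getLogger(__name__)

#: total precedence order over consequences (highest first)
CONSEQUENCE_PRECEDENCE: tuple[str, ...] = (
    "splicing",
    "exonic",
    "UTR5",
    "UTR3",
    "ncRNA_exonic",
    "intronic",
    "ncRNA_intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_PREC = {c: i for i, c in enumerate(CONSEQUENCE_PRECEDENCE)}


@dataclass
class AnnotatedSNP:
    candidate: CandidateSNP
    consequence: str
    annotated_genes: list[tuple[str, int]] = field(default_factory=list)  # (gene_id, signed distance)
    cadd: float | None = None
    rdb: str | None = None
    chromhmm_states: dict[str, int] = field(default_factory=dict)
    catalog_hits: list[CatalogEntry] = field(default_factory=list)

    @property
    def snp_id(self) -> str:
        return self.candidate.variant.snp_id


class GeneIndex:
    """Per-chromosome interval index over gene spans, with optional padding."""

    def __init__(self, genes: list[GeneModel]) -> None:
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            # IntervalTree is half-open; internal coordinates are 1-based inclusive
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def overlapping(self, chrom: str, pos: int, pad: int = 0) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(pos - pad, pos + pad + 1)]
        return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))

    def chrom_genes(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])


def _distance_to_gene(pos: int, g: GeneModel) -> int:
    if pos < g.start:
        return g.start - pos
    if pos > g.end:
        return pos - g.end
    return 0


def _classify_within_gene(pos: int, g: GeneModel, splice_bp: int) -> str:
    in_exon = any(s <= pos <= e for s, e in g.exons)
    coding = g.gene_type == "protein_coding"
    if not in_exon:
        # intronic; splicing when within splice_bp of an exon boundary (intron side)
        near_boundary = any(
            (pos < s and s - pos <= splice_bp) or (pos > e and pos - e <= splice_bp)
            for s, e in g.exons
        )
        if coding and near_boundary:
            return "splicing"
        return "intronic" if coding else "ncRNA_intronic"
    if not coding:
        return "ncRNA_exonic"
    if g.cds_start is not None and g.cds_end is not None:
        if pos < g.cds_start:
            return "UTR5" if g.strand == "+" else "UTR3"
        if pos > g.cds_end:
            return "UTR3" if g.strand == "+" else "UTR5"
    return "exonic"


def classify_consequence(
    chrom: str,
    pos: int,
    index: GeneIndex,
    splice_bp: int = 2,
    flank_bp: int = 1000,
) -> tuple[str, list[tuple[str, int]]]:
    """Classify one position against the gene models.

    Returns (consequence, [(gene_id, signed_distance)]). Signed distance is 0
    inside a gene, negative upstream of the TSS-side, positive downstream —
    for intergenic SNPs the two closest flanking genes are reported with their
    unsigned distances to the gene span, left gene first.
    """
    overlapping = index.overlapping(chrom, pos)
    if overlapping:
        scored = [(_classify_within_gene(pos, g, splice_bp), g) for g in overlapping]
        best = min(_PREC[c] for c, _ in scored)
        consequence = CONSEQUENCE_PRECEDENCE[best]
        return consequence, [(g.gene_id, 0) for _, g in scored]

    genes = index.chrom_genes(chrom)
    if not genes:
        log.warning("no gene models on chromosome %s; %s:%d left intergenic", chrom, chrom, pos)
        return "intergenic", []

    left = [g for g in genes if g.end < pos]
    right = [g for g in genes if g.start > pos]
    nearest_left = max(left, key=lambda g: g.end) if left else None
    nearest_right = min(right, key=lambda g: g.start) if right else None

    # strand-aware flank: upstream of the TSS side, downstream of the tail side
    flank_calls: list[tuple[str, GeneModel, int]] = []
    for g in (nearest_left, nearest_right):
        if g is None:
            continue
        d = _distance_to_gene(pos, g)
        if d > flank_bp:
            continue
        before_gene = pos < g.start
        if g.strand == "+":
            flank_calls.append(("upstream" if before_gene else "downstream", g, d))
        else:
            flank_calls.append(("downstream" if before_gene else "upstream", g, d))
    if flank_calls:
        flank_calls.sort(key=lambda t: (_PREC[t[0]], t[2], t[1].gene_id))
        consequence = flank_calls[0][0]
        return consequence, [(g.gene_id, -d if c == "upstream" else d)
                             for c, g, d in flank_calls]

    out: list[tuple[str, int]] = []
    if nearest_left is not None:
        out.append((nearest_left.gene_id, _distance_to_gene(pos, nearest_left)))
    if nearest_right is not None:
        out.append((nearest_right.gene_id, _distance_to_gene(pos, nearest_right)))
    return "intergenic", out


def annotate_candidates(
    candidates: list[CandidateSNP],
    genes: list[GeneModel] | GeneIndex,
    scores: ScoreTables | None = None,
    epigenomes: list[str] | None = None,
    catalog: list[CatalogEntry] | None = None,
    overrides: dict[str, tuple[str, str]] | None = None,
    splice_bp: int = 2,
    flank_bp: int = 1000,
) -> list[AnnotatedSNP]:
    """Annotate every candidate SNP; pure join, never changes the candidate set.

    ``overrides`` maps snp_id -> (consequence, gene_id) from an external
    consequence table; an override replaces the positional classification.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    catalog_by_pos: dict[tuple[str, int], list[CatalogEntry]] = {}
    for entry in catalog or []:
        catalog_by_pos.setdefault((entry.chrom, entry.pos), []).append(entry)

    out: list[AnnotatedSNP] = []
    for c in candidates:
        v = c.variant
        if overrides and v.snp_id in overrides:
            consequence, gene_id = overrides[v.snp_id]
            if consequence not in _PREC:
                raise ValueError(f"override for {v.snp_id}: unknown consequence {consequence!r}")
            annotated = [(gene_id, 0)]
        else:
            consequence, annotated = classify_consequence(
                v.chrom, v.pos, index, splice_bp=splice_bp, flank_bp=flank_bp)
        ann = AnnotatedSNP(candidate=c, consequence=consequence, annotated_genes=annotated)
        if scores is not None:
            ann.cadd = scores.cadd_of(v.chrom, v.pos, v.ref_allele, v.alt_allele)
            ann.rdb = scores.rdb_of(v.chrom, v.pos)
            for epi in epigenomes or []:
                state = scores.state_of(v.chrom, v.pos, epi)
                if state is not None:
                    ann.chromhmm_states[epi] = state
        ann.catalog_hits = list(catalog_by_pos.get((v.chrom, v.pos), []))
        out.append(ann)
    return out
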