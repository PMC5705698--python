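"""Reference-data model: every external table the pipeline consumes.

All genomic coordinates are held internally as 1-based inclusive intervals
(the convention of GWAS summary statistics and GFF). BED-style half-open
0-based inputs are converted on ingest and converted back on write, so the
conversion lives in exactly one place (:func:`bed_to_internal` /
:func:`internal_to_bed`). Chromosome labels are normalized by stripping a
leading ``chr``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A missing/contradictory configuration item (bad column map, absent tissue...)."""


class ValidationError(ValueError):
    """A malformed input row that cannot be skipped safely (e.g. inverted interval)."""


# ---------------------------------------------------------------------------
# coordinate + label conventions


def normalize_chrom(label: str) -> str:
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


_SPECIAL_CHROM = {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Deterministic genome order: numeric chromosomes, then X/Y/MT, then others."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (int(c), "")
    if c.upper() in _SPECIAL_CHROM:
        return (_SPECIAL_CHROM[c.upper()], "")
    return (100, c)


def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive [start, end]."""
    if end0 <= start0:
        raise ValidationError(f"inverted/empty BED interval ({start0}, {end0})")
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SumstatRecord:
    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    p: float
    beta: float | None = None
    se: float | None = None
    n: int | None = None


@dataclass(frozen=True)
class PanelVariant:
    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    gene_type: str  # protein_coding | ncRNA | other
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = self.start - 1
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end or s <= prev_end:
                raise ValidationError(f"{self.gene_id}: bad exon ({s},{e})")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    def promoter(self, up: int = 250, down: int = 500) -> tuple[int, int]:
        """Strand-aware promoter window around the TSS, 1-based inclusive."""
        if self.strand == "+":
            return self.tss - up, self.tss + down
        return self.tss - down, self.tss + up


@dataclass(frozen=True)
class EqtlRecord:
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    gene_id: str
    tissue: str
    p: float
    fdr: float


@dataclass(frozen=True)
class InteractionRecord:
    """A significant chromatin interaction; both ends stored 1-based inclusive."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    tissue: str
    fdr: float


@dataclass(frozen=True)
class CatalogEntry:
    chrom: str
    pos: int
    trait: str
    reported_p: float | None = None


@dataclass
class EpigenomeRegionSet:
    kind: str  # enhancer | promoter
    epigenome_id: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)  # 1-based incl.

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(c == chrom and s <= end and start <= e for c, s, e in self.intervals)


@dataclass
class GeneSetCollection:
    source_label: str
    sets: dict[str, frozenset[str]] = field(default_factory=dict)


# RegulomeDB ordered vocabulary, best evidence first.
RDB_CATEGORIES: tuple[str, ...] = (
    "1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c",
    "3a", "3b", "4", "5", "6", "7",
)
RDB_RANK: dict[str, int] = {c: i for i, c in enumerate(RDB_CATEGORIES)}

CHROMHMM_BIN = 200  # bp, ChromHMM segmentation resolution


@dataclass
class ScoreTables:
    """CADD / RegulomeDB / chromatin-state lookups with left-join semantics."""

    cadd: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    regulomedb: dict[tuple[str, int], str] = field(default_factory=dict)
    chromhmm: dict[tuple[str, int, str], int] = field(default_factory=dict)

    def cadd_of(self, chrom: str, pos: int, ref: str, alt: str) -> float | None:
        hit = self.cadd.get((chrom, pos, ref, alt))
        if hit is None:  # allele-swapped orientation accepted, strand flips are not
            hit = self.cadd.get((chrom, pos, alt, ref))
        return hit

    def rdb_of(self, chrom: str, pos: int) -> str | None:
        return self.regulomedb.get((chrom, pos))

    def state_of(self, chrom: str, pos: int, epigenome: str) -> int | None:
        return self.chromhmm.get((chrom, (pos - 1) // CHROMHMM_BIN, epigenome))


class LdStore:
    """Symmetric r-squared lookup over a sparse pre-filtered pair table.

    Pairs absent from the table are r2 = 0 (they were below the 0.05 storage
    floor or more than 1 Mb apart when the table was pre-computed); self-LD is
    implicitly 1.
    """

    def __init__(self) -> None:
        self._pairs: dict[tuple[str, str], float] = {}
        self._partners: dict[str, dict[str, float]] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValidationError(f"r2 out of range for ({snp_a},{snp_b}): {r2}")
        if snp_a == snp_b:
            return
        self._pairs[self._key(snp_a, snp_b)] = r2
        self._partners.setdefault(snp_a, {})[snp_b] = r2
        self._partners.setdefault(snp_b, {})[snp_a] = r2

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._pairs.get(self._key(snp_a, snp_b), 0.0)

    def partners(self, snp: str) -> dict[str, float]:
        """All stored partners of ``snp`` (excludes the implicit self-pair)."""
        return dict(self._partners.get(snp, {}))

    def __len__(self) -> int:
        return len(self._pairs)

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for (a, b), r2 in sorted(self._pairs.items()):
            yield a, b, r2


class ExpressionMatrix:
    """Samples x genes RPKM matrix with a sample -> tissue assignment."""

    def __init__(
        self,
        genes: Sequence[str],
        samples: Sequence[str],
        values,  # array-like, shape (len(genes), len(samples)), RPKM >= 0
        tissue_of: Mapping[str, str],
    ) -> None:
        import numpy as np

        self.genes = list(genes)
        self.samples = list(samples)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("expression matrix shape mismatch")
        if (self.values < 0).any():
            raise ValidationError("negative RPKM values")
        missing = [s for s in self.samples if s not in tissue_of]
        if missing:
            raise ValidationError(f"samples without tissue assignment: {missing[:5]}")
        self.tissue_of = {s: tissue_of[s] for s in self.samples}
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.tissue_of[s], None)
        return list(seen)

    def sample_columns(self, tissue: str) -> list[int]:
        return [i for i, s in enumerate(self.samples) if self.tissue_of[s] == tissue]


@dataclass
class Parameters:
    """Pipeline thresholds. Defaults are the published defaults of the method."""

    p_sig: float = 5e-8
    r2_ind: float = 0.6
    r2_lead: float = 0.1
    merge_kb: float = 250.0
    maf_min: float = 0.01
    pos_window_kb: float = 10.0
    cadd_min: float | None = None        # 12.37 in the deleterious-coding preset
    eqtl_fdr_max: float = 0.05
    eqtl_p_max: float | None = None
    ci_fdr_max: float = 1e-6
    promoter_up: int = 250
    promoter_down: int = 500
    expr_min_rpkm: float = 1.0
    winsor_cap: float = 50.0
    deg_alpha: float = 0.05
    deg_lfc: float = 0.58
    enrich_adjp: float = 0.05
    enrich_min_overlap: int = 2

    def __post_init__(self) -> None:
        if self.r2_lead > self.r2_ind:
            raise ConfigError("r2_lead must be <= r2_ind")
        for name in ("p_sig", "r2_ind", "merge_kb", "maf_min", "eqtl_fdr_max",
                     "ci_fdr_max", "deg_alpha", "deg_lfc", "enrich_adjp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"parameter {name} must be positive")

    @classmethod
    def from_mapping(cls, d: Mapping[str, object]) -> "Parameters":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)  # type: ignore[arg-type]


@dataclass
class ReferenceBundle:
    """Everything the pipeline needs besides the summary statistics."""

    panel: dict[str, PanelVariant] = field(default_factory=dict)
    ld: LdStore = field(default_factory=LdStore)
    genes: list[GeneModel] = field(default_factory=list)
    scores: ScoreTables = field(default_factory=ScoreTables)
    eqtls: list[EqtlRecord] = field(default_factory=list)
    interactions: list[InteractionRecord] = field(default_factory=list)
    regions: list[EpigenomeRegionSet] = field(default_factory=list)
    expression: ExpressionMatrix | None = None
    gene_sets: list[GeneSetCollection] = field(default_factory=list)
    catalog: list[CatalogEntry] = field(default_factory=list)
    pli: dict[str, float] = field(default_factory=dict)
    ncrvis: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# summary-statistics reader

#: header synonyms accepted without an explicit column map
SUMSTAT_SYNONYMS: dict[str, tuple[str, ...]] = {
    "snp_id": ("snp", "snpid", "rsid", "markername", "marker", "id"),
    "chrom": ("chr", "chrom", "chromosome"),
    "pos": ("bp", "pos", "position", "bp_hg19"),
    "effect_allele": ("a1", "effect_allele", "ea", "alt"),
    "other_allele": ("a2", "other_allele", "oa", "ref", "nea"),
    "p": ("p", "pval", "pvalue", "p_value", "p-value"),
    "beta": ("beta", "b", "effect"),
    "se": ("se", "stderr"),
    "n": ("n", "nsample", "n_total"),
}
_REQUIRED_SUMSTAT = ("snp_id", "chrom", "pos", "effect_allele", "other_allele", "p")


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str] | None):
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    for canon, synonyms in SUMSTAT_SYNONYMS.items():
        if column_map and canon in column_map:
            if column_map[canon] not in header:
                raise ConfigError(f"mapped column {column_map[canon]!r} for {canon!r} not in header")
            resolved[canon] = column_map[canon]
            continue
        for syn in synonyms:
            if syn in lower:
                resolved[canon] = lower[syn]
                break
    missing = [c for c in _REQUIRED_SUMSTAT if c not in resolved]
    if missing:
        raise ConfigError(f"required summary-statistic column(s) not found: {missing}")
    return resolved


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    report: dict | None = None,
) -> list[SumstatRecord]:
    """Read delimited GWAS summary statistics into validated records.

    Malformed rows (p outside (0,1], non-numeric fields, duplicate
    (chrom,pos,alleles)) are skipped with a log entry and counted into
    ``report`` if a dict is supplied. A missing required column raises
    :class:`ConfigError`.
    """
    records: list[SumstatRecord] = []
    seen: set[tuple] = set()
    skipped = 0
    with open(path, newline="") as fh:
        if sep is None:
            sample = fh.readline()
            sep = "\t" if "\t" in sample else (
                "," if "," in sample else None)
            fh.seek(0)
            if sep is None:
                reader = csv.DictReader(fh, delimiter=" ", skipinitialspace=True)
            else:
                reader = csv.DictReader(fh, delimiter=sep)
        else:
            reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None:
            raise ConfigError(f"{path}: empty file")
        cols = _resolve_columns(reader.fieldnames, column_map)
        for lineno, row in enumerate(reader, start=2):
            try:
                p = float(row[cols["p"]])
                if not 0.0 < p <= 1.0:
                    raise ValueError(f"p={p} outside (0,1]")
                ea = row[cols["effect_allele"]].strip().upper()
                oa = row[cols["other_allele"]].strip().upper()
                if not ea or not oa or ea == oa:
                    raise ValueError("alleles empty or identical")
                rec = SumstatRecord(
                    snp_id=row[cols["snp_id"]].strip(),
                    chrom=normalize_chrom(row[cols["chrom"]]),
                    pos=int(row[cols["pos"]]),
                    effect_allele=ea,
                    other_allele=oa,
                    p=p,
                    beta=float(row[cols["beta"]]) if cols.get("beta") and row.get(cols["beta"], "") not in ("", "NA") else None,
                    se=float(row[cols["se"]]) if cols.get("se") and row.get(cols["se"], "") not in ("", "NA") else None,
                    n=int(float(row[cols["n"]])) if cols.get("n") and row.get(cols["n"], "") not in ("", "NA") else None,
                )
                if rec.pos < 1:
                    raise ValueError("pos < 1")
                key = (rec.chrom, rec.pos, frozenset((rec.effect_allele, rec.other_allele)))
                if key in seen:
                    raise ValueError("duplicate (chrom,pos,alleles)")
                seen.add(key)
            except (ValueError, KeyError) as exc:
                skipped += 1
                log.warning("%s:%d skipped: %s", path, lineno, exc)
                continue
            records.append(rec)
    if report is not None:
        report["n_read"] = len(records)
        report["n_skipped"] = skipped
    return records


# ---------------------------------------------------------------------------
# reference-table readers (plain delimited text, one row per record)


def _tsv_rows(path):
    with open(path, newline="") as fh:
        yield from csv.DictReader(fh, delimiter="\t")


def read_panel(path) -> dict[str, PanelVariant]:
    """snp_id / chrom / pos / ref / alt / maf, tab-separated with header."""
    out: dict[str, PanelVariant] = {}
    seen: set[tuple] = set()
    for row in _tsv_rows(path):
        maf = float(row["maf"])
        if not 0.0 <= maf <= 0.5:
            raise ValidationError(f"{path}: maf {maf} outside [0, 0.5] for {row['snp_id']}")
        v = PanelVariant(row["snp_id"], normalize_chrom(row["chrom"]), int(row["pos"]),
                         row["ref"].upper(), row["alt"].upper(), maf)
        key = (v.chrom, v.pos, v.ref_allele, v.alt_allele)
        if key in seen:
            raise ValidationError(f"{path}: duplicate panel variant {key}")
        seen.add(key)
        out[v.snp_id] = v
    return out


def read_ld(path, panel: Mapping[str, PanelVariant] | None = None) -> LdStore:
    """snp_a / snp_b / r2 table; optionally validated against the pre-filter contract."""
    store = LdStore()
    for row in _tsv_rows(path):
        a, b, r2 = row["snp_a"], row["snp_b"], float(row["r2"])
        if r2 < 0.05:
            raise ValidationError(f"{path}: stored pair ({a},{b}) below the r2=0.05 floor")
        if panel is not None and a in panel and b in panel:
            va, vb = panel[a], panel[b]
            if va.chrom == vb.chrom and abs(va.pos - vb.pos) > 1_000_000:
                raise ValidationError(f"{path}: pair ({a},{b}) further than 1 Mb apart")
        store.add(a, b, r2)
    return store


def read_gene_models(path) -> list[GeneModel]:
    """BED12 (0-based half-open) or a delimited gene table (1-based inclusive).

    The delimited variant has columns gene_id/symbol/gene_type/chrom/start/end/
    strand/exon_starts/exon_ends[/cds_start/cds_end] with comma-joined exon
    coordinate lists.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(("#", "track")) or (first and "\t" in first and not first.lower().startswith("gene_id")):
        return _read_bed12(path)
    for row in _tsv_rows(path):
        starts = [int(x) for x in row["exon_starts"].split(",") if x]
        ends = [int(x) for x in row["exon_ends"].split(",") if x]
        genes.append(GeneModel(
            gene_id=row["gene_id"], symbol=row["symbol"], gene_type=row["gene_type"],
            chrom=normalize_chrom(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
            strand=row["strand"], exons=tuple(zip(starts, ends)),
            cds_start=int(row["cds_start"]) if row.get("cds_start") not in (None, "", "NA") else None,
            cds_end=int(row["cds_end"]) if row.get("cds_end") not in (None, "", "NA") else None,
        ))
    return genes


def _read_bed12(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValidationError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom = normalize_chrom(f[0])
            start, end = bed_to_internal(int(f[1]), int(f[2]))
            name = f[3]
            gene_id, _, rest = name.partition("|")
            symbol, _, gene_type = rest.partition("|")
            strand = f[5]
            thick_s0, thick_e0 = int(f[6]), int(f[7])
            n_exons = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_exons or len(offsets) != n_exons:
                raise ValidationError(f"{path}:{lineno}: exon block count mismatch")
            exons = tuple(
                bed_to_internal(int(f[1]) + off, int(f[1]) + off + size)
                for off, size in zip(offsets, sizes)
            )
            cds = None if thick_e0 <= thick_s0 else bed_to_internal(thick_s0, thick_e0)
            genes.append(GeneModel(
                gene_id=gene_id, symbol=symbol or gene_id,
                gene_type=gene_type or "protein_coding", chrom=chrom,
                start=start, end=end, strand=strand, exons=exons,
                cds_start=cds[0] if cds else None, cds_end=cds[1] if cds else None,
            ))
    return genes


def read_score_tables(cadd_path=None, rdb_path=None, chromhmm_path=None) -> ScoreTables:
    """CADD: chrom/pos/ref/alt/score. RegulomeDB: chrom/pos/category.
    ChromHMM: chrom/bin_start(0-based, multiple of 200)/epigenome/state."""
    t = ScoreTables()
    if cadd_path:
        for row in _tsv_rows(cadd_path):
            t.cadd[(normalize_chrom(row["chrom"]), int(row["pos"]),
                    row["ref"].upper(), row["alt"].upper())] = float(row["score"])
    if rdb_path:
        for row in _tsv_rows(rdb_path):
            cat = row["category"]
            if cat not in RDB_RANK:
                raise ValidationError(f"{rdb_path}: unknown RegulomeDB category {cat!r}")
            t.regulomedb[(normalize_chrom(row["chrom"]), int(row["pos"]))] = cat
    if chromhmm_path:
        for row in _tsv_rows(chromhmm_path):
            state = int(row["state"])
            if not 1 <= state <= 15:
                raise ValidationError(f"{chromhmm_path}: state {state} outside 1..15")
            bin_start = int(row["bin_start"])
            t.chromhmm[(normalize_chrom(row["chrom"]), bin_start // CHROMHMM_BIN,
                        row["epigenome"])] = state
    return t


def read_eqtls(path) -> list[EqtlRecord]:
    """chrom/pos/effect_allele/other_allele/gene_id/tissue/p/fdr."""
    out = []
    for row in _tsv_rows(path):
        p = float(row["p"])
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"{path}: eQTL p={p} outside (0,1]")
        out.append(EqtlRecord(normalize_chrom(row["chrom"]), int(row["pos"]),
                              row["effect_allele"].upper(), row["other_allele"].upper(),
                              row["gene_id"], row["tissue"], p, float(row["fdr"])))
    return out


def read_interactions(path) -> list[InteractionRecord]:
    """BEDPE (+ tissue and fdr columns 7/8): both ends 0-based half-open on disk."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValidationError(f"{path}:{lineno}: BEDPE needs chrom/start/end x2 + tissue + fdr")
            try:
                sa, ea = bed_to_internal(int(f[1]), int(f[2]))
                sb, eb = bed_to_internal(int(f[4]), int(f[5]))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            out.append(InteractionRecord(normalize_chrom(f[0]), sa, ea,
                                         normalize_chrom(f[3]), sb, eb,
                                         f[6], float(f[7])))
    return out


def read_regions(path, kind: str, epigenome_id: str) -> EpigenomeRegionSet:
    """Plain BED intervals for one epigenome's predicted enhancers or promoters."""
    if kind not in ("enhancer", "promoter"):
        raise ConfigError(f"region kind must be enhancer|promoter, got {kind!r}")
    rs = EpigenomeRegionSet(kind=kind, epigenome_id=epigenome_id)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                s, e = bed_to_internal(int(f[1]), int(f[2]))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
            rs.intervals.append((normalize_chrom(f[0]), s, e))
    return rs


def read_expression(matrix_path, tissue_map_path) -> ExpressionMatrix:
    """Genes x samples RPKM matrix (TSV, first column gene_id) plus a two-column
    sample/tissue map."""
    import pandas as pd

    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    tmap = pd.read_csv(tissue_map_path, sep="\t")
    tissue_of = dict(zip(tmap.iloc[:, 0].astype(str), tmap.iloc[:, 1].astype(str)))
    return ExpressionMatrix(list(mat.index.astype(str)), list(mat.columns.astype(str)),
                            mat.to_numpy(), tissue_of)


def read_gmt(path, source_label: str) -> GeneSetCollection:
    coll = GeneSetCollection(source_label=source_label)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValidationError(f"{path}: GMT line needs name, description, >=1 member")
            coll.sets[f[0]] = frozenset(g for g in f[2:] if g)
    return coll


def read_catalog(path) -> list[CatalogEntry]:
    out = []
    for row in _tsv_rows(path):
        rp = row.get("reported_p")
        out.append(CatalogEntry(normalize_chrom(row["chrom"]), int(row["pos"]),
                                row["trait"], float(rp) if rp not in (None, "", "NA") else None))
    return out


def read_score_map(path) -> dict[str, float]:
    """Two-column gene_id/score table (pLI, ncRVIS)."""
    out = {}
    for row in _tsv_rows(path):
        keys = list(row)
        out[row[keys[0]]] = float(row[keys[1]])
    return out


# ---------------------------------------------------------------------------
# writers (exact inverses of the readers; used by the fixture generator and
# exercised by the round-trip tests)


def _write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def write_sumstats(path, records: Iterable[SumstatRecord]) -> None:
    _write_tsv(path, ["SNP", "CHR", "BP", "A1", "A2", "P", "BETA", "SE", "N"],
               [(r.snp_id, r.chrom, r.pos, r.effect_allele, r.other_allele,
                 repr(r.p),
                 "" if r.beta is None else repr(r.beta),
                 "" if r.se is None else repr(r.se),
                 "" if r.n is None else r.n) for r in records])


def write_panel(path, panel: Mapping[str, PanelVariant]) -> None:
    _write_tsv(path, ["snp_id", "chrom", "pos", "ref", "alt", "maf"],
               [(v.snp_id, v.chrom, v.pos, v.ref_allele, v.alt_allele, repr(v.maf))
                for v in panel.values()])


def write_ld(path, ld: LdStore) -> None:
    _write_tsv(path, ["snp_a", "snp_b", "r2"],
               [(a, b, repr(r2)) for a, b, r2 in ld.pairs()])


def write_gene_models(path, genes: Iterable[GeneModel]) -> None:
    _write_tsv(path, ["gene_id", "symbol", "gene_type", "chrom", "start", "end",
                      "strand", "exon_starts", "exon_ends", "cds_start", "cds_end"],
               [(g.gene_id, g.symbol, g.gene_type, g.chrom, g.start, g.end, g.strand,
                 ",".join(str(s) for s, _ in g.exons),
                 ",".join(str(e) for _, e in g.exons),
                 "" if g.cds_start is None else g.cds_start,
                 "" if g.cds_end is None else g.cds_end) for g in genes])


def write_score_tables(t: ScoreTables, cadd_path=None, rdb_path=None, chromhmm_path=None) -> None:
    if cadd_path:
        _write_tsv(cadd_path, ["chrom", "pos", "ref", "alt", "score"],
                   [(c, p, r, a, repr(s)) for (c, p, r, a), s in sorted(t.cadd.items())])
    if rdb_path:
        _write_tsv(rdb_path, ["chrom", "pos", "category"],
                   [(c, p, cat) for (c, p), cat in sorted(t.regulomedb.items())])
    if chromhmm_path:
        _write_tsv(chromhmm_path, ["chrom", "bin_start", "epigenome", "state"],
                   [(c, b * CHROMHMM_BIN, e, s)
                    for (c, b, e), s in sorted(t.chromhmm.items())])


def write_eqtls(path, eqtls: Iterable[EqtlRecord]) -> None:
    _write_tsv(path, ["chrom", "pos", "effect_allele", "other_allele", "gene_id",
                      "tissue", "p", "fdr"],
               [(q.chrom, q.pos, q.effect_allele, q.other_allele, q.gene_id,
                 q.tissue, repr(q.p), repr(q.fdr)) for q in eqtls])


def write_interactions(path, records: Iterable[InteractionRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            sa0, ea0 = internal_to_bed(r.start_a, r.end_a)
            sb0, eb0 = internal_to_bed(r.start_b, r.end_b)
            fh.write(f"{r.chrom_a}\t{sa0}\t{ea0}\t{r.chrom_b}\t{sb0}\t{eb0}\t{r.tissue}\t{r.fdr!r}\n")


def write_regions(path, rs: EpigenomeRegionSet) -> None:
    with open(path, "w") as fh:
        for c, s, e in rs.intervals:
            s0, e0 = internal_to_bed(s, e)
            fh.write(f"{c}\t{s0}\t{e0}\n")


def write_expression(matrix_path, tissue_map_path, expr: ExpressionMatrix) -> None:
    import pandas as pd

    pd.DataFrame(expr.values, index=pd.Index(expr.genes, name="gene_id"),
                 columns=expr.samples).to_csv(matrix_path, sep="\t")
    _write_tsv(tissue_map_path, ["sample", "tissue"],
               [(s, expr.tissue_of[s]) for s in expr.samples])


def write_gmt(path, coll: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.sets):
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{coll.source_label}\t{members}\n")


def write_catalog(path, entries: Iterable[CatalogEntry]) -> None:
    _write_tsv(path, ["chrom", "pos", "trait", "reported_p"],
               [(e.chrom, e.pos, e.trait, "" if e.reported_p is None else repr(e.reported_p))
                for e in entries])


def write_score_map(path, scores: Mapping[str, float], colname: str) -> None:
    _write_tsv(path, ["gene_id", colname],
               [(g, repr(s)) for g, s in sorted(scores.items())])
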