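"""Orchestration of the two end-to-end flows and their on-disk reports.

``run_snp2gene`` chains locus characterization, SNP annotation and gene
mapping; ``run_gene2func`` chains expression filtering, summaries, DEG sets
and the enrichment tests. Both are deterministic given inputs and
configuration, and both leave a run log recording every parameter, the
checksum of every input file, and the row counts each filter removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import gene2func, genemap, loci as loci_mod, refdata, snpannot
from .refdata import ConfigError, Parameters, ReferenceBundle

log = logging.getLogger(__name__)

_PATH_KEYS = (
    "sumstats", "panel", "ld", "genes", "cadd", "regulomedb", "chromhmm",
    "eqtls", "interactions", "enhancers", "promoters", "expression",
    "tissue_map", "catalog", "pli", "ncrvis", "predefined_leads", "regions",
    "consequence_overrides",
)


@dataclass
class RunConfig:
    paths: dict[str, str] = field(default_factory=dict)
    gmt: dict[str, str] = field(default_factory=dict)   # source_label -> path
    params: Parameters = field(default_factory=Parameters)
    eqtl_tissues: list[str] = field(default_factory=list)
    ci_tissues: list[str] = field(default_factory=list)
    epigenomes: list[str] = field(default_factory=list)
    strategies: dict[str, bool] = field(
        default_factory=lambda: {"positional": True, "eqtl": True, "chromatin": True})
    positional_mode: str = "window"      # window | consequence
    positional_consequences: list[str] = field(default_factory=list)
    pos_filter: dict = field(default_factory=dict)   # per-strategy functional filters
    eqtl_filter: dict = field(default_factory=dict)
    ci_filter: dict = field(default_factory=dict)
    use_enhancer_filter: bool = False
    use_promoter_filter: bool = False
    magma_binary: str | None = None
    out_dir: str = "out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw, base=Path(path).parent)

    @classmethod
    def from_mapping(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        params = Parameters.from_mapping(raw.pop("params", {}) or {})
        cfg = cls(params=params, **{k: v for k, v in raw.items() if k != "params"})
        if base is not None:
            cfg.paths = {k: str((base / v)) if not Path(v).is_absolute() else v
                         for k, v in cfg.paths.items()}
            cfg.gmt = {k: str((base / v)) if not Path(v).is_absolute() else v
                       for k, v in cfg.gmt.items()}
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in self.paths:
            if key not in _PATH_KEYS:
                raise ConfigError(f"unknown input path key {key!r}")
        for key, p in list(self.paths.items()) + list(self.gmt.items()):
            if not Path(p).exists():
                raise ConfigError(f"input path for {key!r} does not exist: {p}")
        if not any(self.strategies.values()):
            raise ConfigError("at least one mapping strategy must be enabled")
        if self.positional_mode not in ("window", "consequence"):
            raise ConfigError("positional_mode must be 'window' or 'consequence'")

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_reference(cfg: RunConfig) -> ReferenceBundle:
    p = cfg.paths
    bundle = ReferenceBundle()
    if "panel" in p:
        bundle.panel = refdata.read_panel(p["panel"])
    if "ld" in p:
        bundle.ld = refdata.read_ld(p["ld"], panel=bundle.panel or None)
    if "genes" in p:
        bundle.genes = refdata.read_gene_models(p["genes"])
    bundle.scores = refdata.read_score_tables(
        cadd_path=p.get("cadd"), rdb_path=p.get("regulomedb"),
        chromhmm_path=p.get("chromhmm"))
    if "eqtls" in p:
        bundle.eqtls = refdata.read_eqtls(p["eqtls"])
    if "interactions" in p:
        bundle.interactions = refdata.read_interactions(p["interactions"])
    for key, kind in (("enhancers", "enhancer"), ("promoters", "promoter")):
        if key in p:
            epi = Path(p[key]).name.split(".")[-2] if "." in Path(p[key]).name else "E000"
            bundle.regions.append(refdata.read_regions(p[key], kind, epi))
    if "expression" in p and "tissue_map" in p:
        bundle.expression = refdata.read_expression(p["expression"], p["tissue_map"])
    for label, path in cfg.gmt.items():
        bundle.gene_sets.append(refdata.read_gmt(path, label))
    if "catalog" in p:
        bundle.catalog = refdata.read_catalog(p["catalog"])
    if "pli" in p:
        bundle.pli = refdata.read_score_map(p["pli"])
    if "ncrvis" in p:
        bundle.ncrvis = refdata.read_score_map(p["ncrvis"])
    return bundle


def _write_run_log(out: Path, cfg: RunConfig, counts: dict) -> None:
    payload = {
        "config": cfg.to_mapping(),
        "input_checksums": {k: _sha256(v) for k, v in
                            list(cfg.paths.items()) + list(cfg.gmt.items())},
        "counts": counts,
    }
    with open(out / "run.log", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_run_log(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _maybe_run_magma(cfg: RunConfig, out: Path) -> None:
    if not cfg.magma_binary:
        return
    if shutil.which(cfg.magma_binary) is None:
        log.warning("MAGMA binary %r not found; gene-based analysis skipped",
                    cfg.magma_binary)
        (out / "magma.skipped").write_text("binary not found\n")
        return
    subprocess.run([cfg.magma_binary, "--version"], check=False,
                   capture_output=True)


def run_snp2gene(cfg: RunConfig, out_dir=None) -> Path:
    """Loci -> annotation -> gene mapping; writes the downloadable tables."""
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    report: dict = {}
    sumstats = refdata.read_sumstats(cfg.paths["sumstats"], report=report)
    counts.update({"sumstats_read": report.get("n_read", 0),
                   "sumstats_skipped": report.get("n_skipped", 0)})
    bundle = load_reference(cfg)

    predefined = None
    if "predefined_leads" in cfg.paths:
        predefined = [l.strip() for l in open(cfg.paths["predefined_leads"])
                      if l.strip() and not l.startswith("#")]
    regions = None
    if "regions" in cfg.paths:
        regions = []
        with open(cfg.paths["regions"]) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    c, s, e = line.split()[:3]
                    regions.append((refdata.normalize_chrom(c), int(s), int(e)))

    params = cfg.params
    ind_sig, leads, candidates, risk_loci = loci_mod.characterize(
        sumstats, bundle.panel, bundle.ld, params,
        predefined_leads=predefined, regions=regions)
    counts.update({"ind_sig": len(ind_sig), "leads": len(leads),
                   "candidates": len(candidates), "loci": len(risk_loci)})

    overrides = None
    if "consequence_overrides" in cfg.paths:
        overrides = {}
        for row in pd.read_csv(cfg.paths["consequence_overrides"], sep="\t").itertuples():
            overrides[str(row.snp_id)] = (str(row.consequence), str(row.gene_id))

    gene_index = snpannot.GeneIndex(bundle.genes)
    annotated = snpannot.annotate_candidates(
        candidates, gene_index, scores=bundle.scores,
        epigenomes=cfg.epigenomes, catalog=bundle.catalog, overrides=overrides)

    evidence = {"positional": None, "eqtl": None, "chromatin": None}
    if cfg.strategies.get("positional"):
        subset = genemap.filter_snps_functional(annotated, **cfg.pos_filter)
        if cfg.positional_mode == "consequence":
            evidence["positional"] = genemap.positional_map(
                subset, gene_index,
                allowed_consequences=set(cfg.positional_consequences)
                or {"exonic", "splicing"})
        else:
            evidence["positional"] = genemap.positional_map(
                subset, gene_index, window_kb=params.pos_window_kb)
    if cfg.strategies.get("eqtl") and bundle.eqtls:
        subset = genemap.filter_snps_functional(annotated, **cfg.eqtl_filter)
        tissues = cfg.eqtl_tissues or sorted({q.tissue for q in bundle.eqtls})
        evidence["eqtl"] = genemap.eqtl_map(
            subset, bundle.eqtls, gene_index, tissues,
            fdr_max=params.eqtl_fdr_max, p_max=params.eqtl_p_max)
    if cfg.strategies.get("chromatin") and bundle.interactions:
        subset = genemap.filter_snps_functional(annotated, **cfg.ci_filter)
        tissues = cfg.ci_tissues or sorted({r.tissue for r in bundle.interactions})
        enh = [r for r in bundle.regions if r.kind == "enhancer"] or None
        prom = [r for r in bundle.regions if r.kind == "promoter"] or None
        evidence["chromatin"] = genemap.chromatin_map(
            subset, bundle.interactions, gene_index, tissues,
            ci_fdr_max=params.ci_fdr_max,
            promoter_up=params.promoter_up, promoter_down=params.promoter_down,
            enhancer_sets=enh if cfg.use_enhancer_filter else None,
            promoter_sets=prom if cfg.use_promoter_filter else None)

    mapped = genemap.combine_maps(
        evidence["positional"], evidence["eqtl"], evidence["chromatin"],
        risk_loci, gene_index, pli=bundle.pli, ncrvis=bundle.ncrvis)
    counts["mapped_genes"] = len(mapped)

    _write_tables(out, ind_sig, leads, candidates, risk_loci, annotated, mapped,
                  evidence)
    _maybe_run_magma(cfg, out)
    _write_run_log(out, cfg, counts)
    return out


def _write_tables(out, ind_sig, leads, candidates, risk_loci, annotated, mapped,
                  evidence) -> None:
    pd.DataFrame([
        {"locus": l.locus_id, "chr": l.chrom, "start": l.start, "end": l.end,
         "top_snp": l.top_snp.snp_id, "p": l.top_snp.p,
         "n_ind_sig": len(l.ind_sig_snps), "n_lead": len(l.lead_snps),
         "n_candidates": l.n_candidates}
        for l in risk_loci
    ], columns=["locus", "chr", "start", "end", "top_snp", "p", "n_ind_sig",
                "n_lead", "n_candidates"]).to_csv(
        out / "GenomicRiskLoci.txt", sep="\t", index=False)

    pd.DataFrame([
        {"snp": i.snp.snp_id, "chr": i.snp.chrom, "pos": i.snp.pos,
         "p": i.snp.p, "rank": i.rank, "forced": i.forced}
        for i in ind_sig
    ], columns=["snp", "chr", "pos", "p", "rank", "forced"]).to_csv(
        out / "IndSigSNPs.txt", sep="\t", index=False)

    pd.DataFrame([
        {"snp": l.snp.snp_id, "chr": l.snp.chrom, "pos": l.snp.pos, "p": l.snp.p,
         "member_ind_sig": ";".join(l.member_ind_sig), "forced": l.forced}
        for l in leads
    ], columns=["snp", "chr", "pos", "p", "member_ind_sig", "forced"]).to_csv(
        out / "leadSNPs.txt", sep="\t", index=False)

    locus_of = {}
    for l in risk_loci:
        for c in l.candidates:
            locus_of[c.variant.snp_id] = l.locus_id
    pd.DataFrame([
        {"snp": c.variant.snp_id, "chr": c.variant.chrom, "pos": c.variant.pos,
         "p": "" if c.p is None else c.p, "maf": c.variant.maf,
         "best_r2": c.best_r2, "nearest_ind_sig": c.nearest_ind_sig,
         "gwas_tagged": c.gwas_tagged, "locus": locus_of.get(c.variant.snp_id, "")}
        for c in candidates
    ], columns=["snp", "chr", "pos", "p", "maf", "best_r2", "nearest_ind_sig",
                "gwas_tagged", "locus"]).to_csv(
        out / "snps.txt", sep="\t", index=False)

    pd.DataFrame([
        {"snp": a.snp_id, "consequence": a.consequence,
         "genes": ";".join(f"{g}:{d}" for g, d in a.annotated_genes),
         "cadd": "" if a.cadd is None else a.cadd,
         "rdb": a.rdb or "",
         "chromhmm": ";".join(f"{e}:{s}" for e, s in sorted(a.chromhmm_states.items())),
         "catalog_traits": ";".join(h.trait for h in a.catalog_hits)}
        for a in annotated
    ], columns=["snp", "consequence", "genes", "cadd", "rdb", "chromhmm",
                "catalog_traits"]).to_csv(out / "annot.txt", sep="\t", index=False)

    genemap.gene_table(mapped).to_csv(out / "genes.txt", sep="\t", index=False)

    eq = evidence.get("eqtl") or {}
    pd.DataFrame([
        {"gene_id": g, "snps": ";".join(sorted(ev.snp_ids)),
         "tissues": ";".join(sorted(ev.detail.get("tissues", ()))),
         "min_fdr": ev.detail.get("min_fdr", ""), "min_p": ev.detail.get("min_p", "")}
        for g, ev in sorted(eq.items())
    ], columns=["gene_id", "snps", "tissues", "min_fdr", "min_p"]).to_csv(
        out / "eqtl.txt", sep="\t", index=False)

    ci = evidence.get("chromatin") or {}
    pd.DataFrame([
        {"gene_id": g, "snps": ";".join(sorted(ev.snp_ids)),
         "tissues": ";".join(sorted(ev.detail.get("tissues", ()))),
         "min_fdr": ev.detail.get("min_fdr", ""),
         "promoter_promoter": ev.detail.get("promoter_promoter", False)}
        for g, ev in sorted(ci.items())
    ], columns=["gene_id", "snps", "tissues", "min_fdr", "promoter_promoter"]).to_csv(
        out / "ci.txt", sep="\t", index=False)


def resolve_gene_ids(ids: list[str], genes) -> tuple[list[str], list[str]]:
    """Resolve a mixed symbol/stable-id list against the gene models."""
    by_id = {g.gene_id for g in genes}
    by_symbol: dict[str, str] = {}
    for g in genes:
        by_symbol.setdefault(g.symbol, g.gene_id)
    resolved, unknown = [], []
    for x in ids:
        if x in by_id:
            resolved.append(x)
        elif x in by_symbol:
            resolved.append(by_symbol[x])
        else:
            unknown.append(x)
    return resolved, unknown


def run_gene2func(cfg: RunConfig, gene_list: list[str] | None = None,
                  gene_list_path=None, background: set[str] | None = None,
                  out_dir=None) -> Path:
    """Expression filter -> summaries -> DEG sets -> enrichments."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    counts: dict[str, int] = {}
    bundle = load_reference(cfg)
    if bundle.expression is None:
        raise ConfigError("gene2func needs expression + tissue_map inputs")

    if gene_list is None:
        if gene_list_path is None:
            raise ConfigError("gene2func needs a gene list")
        gene_list = [l.strip() for l in open(gene_list_path)
                     if l.strip() and not l.startswith("#")]
    resolved, unknown = resolve_gene_ids(gene_list, bundle.genes)
    if not resolved:
        raise ConfigError("no input gene could be resolved against the gene models")
    out.mkdir(parents=True, exist_ok=True)
    if unknown:
        log.warning("%d gene ids could not be resolved: %s", len(unknown), unknown[:10])
        (out / "unresolved_genes.txt").write_text("\n".join(unknown) + "\n")
    counts.update({"genes_in": len(gene_list), "genes_resolved": len(resolved),
                   "genes_unresolved": len(unknown)})

    params = cfg.params
    expressed = gene2func.filter_expressed(bundle.expression, min_rpkm=params.expr_min_rpkm)
    counts["genes_expressed"] = len(expressed)
    summary = gene2func.summarize_expression(bundle.expression, genes=expressed,
                                             winsor_cap=params.winsor_cap)
    summary.to_csv(out / "gtex_summary.txt", sep="\t", index=False)

    deg = gene2func.build_deg_sets(bundle.expression, genes=expressed,
                                   deg_alpha=params.deg_alpha, deg_lfc=params.deg_lfc)
    deg.stats.to_csv(out / "deg.txt", sep="\t", index=False)

    if background is None:
        background = {g.gene_id for g in bundle.genes if g.gene_type == "protein_coding"}
    counts["background"] = len(background)

    deg_full, deg_report = gene2func.enrich_deg(
        resolved, deg, background, adjp_max=params.enrich_adjp,
        min_overlap=params.enrich_min_overlap)
    deg_full.to_csv(out / "DEG_enrichment_full.txt", sep="\t", index=False)
    deg_report.to_csv(out / "DEG_enrichment.txt", sep="\t", index=False)

    if bundle.gene_sets:
        gs_full, gs_report = gene2func.enrich_gene_sets(
            resolved, bundle.gene_sets, background,
            adjp_max=params.enrich_adjp, min_overlap=params.enrich_min_overlap)
    else:
        gs_full = gs_report = pd.DataFrame(
            columns=["source", "set_name", "N", "K", "n", "k", "p", "adj_p",
                     "overlap_genes"])
    gs_full.to_csv(out / "GS_enrichment_full.txt", sep="\t", index=False)
    gs_report.to_csv(out / "GS_enrichment.txt", sep="\t", index=False)

    _write_run_log(out, cfg, counts)
    return out
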