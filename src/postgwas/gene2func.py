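"""Biological characterization of a prioritized gene list.

Expression summaries per gene x tissue (winsorized log2 means and their
within-gene centering), tissue differentially-expressed-gene (DEG) sets from
two-sided pooled-variance t-tests of one tissue against all others, and
hypergeometric over-representation tests of the input genes against gene-set
collections and the DEG sets, with multiple-testing adjustment applied within
each data source.

The hypergeometric upper-tail probability — the statistic everything here
rests on — is computed in log space from gamma functions; scipy's survival
function serves as an independent cross-check in the test suite, not as the
implementation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .refdata import ConfigError, ExpressionMatrix, GeneSetCollection

log = logging.getLogger(__name__)

_TINY_P = 5e-324  # smallest subnormal double; stands in for p -> 0 degeneracies


# ---------------------------------------------------------------------------
# expression summaries


def filter_expressed(expr: ExpressionMatrix, min_rpkm: float = 1.0) -> list[str]:
    """Genes whose mean raw RPKM reaches ``min_rpkm`` in at least one tissue."""
    keep = []
    cols_by_tissue = {t: expr.sample_columns(t) for t in expr.tissues}
    for t, cols in cols_by_tissue.items():
        if not cols:
            raise ConfigError(f"tissue {t!r} has no samples")
    for i, gene in enumerate(expr.genes):
        if any(expr.values[i, cols].mean() >= min_rpkm for cols in cols_by_tissue.values()):
            keep.append(gene)
    return keep


def summarize_expression(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    winsor_cap: float = 50.0,
) -> pd.DataFrame:
    """Per gene x tissue: ``mean_log`` = mean over tissue samples of
    log2(min(RPKM, cap) + 1), and ``norm_log`` = mean_log centered to zero
    mean across tissues within the gene."""
    genes = list(expr.genes) if genes is None else genes
    tissues = expr.tissues
    cols = {t: expr.sample_columns(t) for t in tissues}
    idx = {g: i for i, g in enumerate(expr.genes)}
    logv = np.log2(np.minimum(expr.values, winsor_cap) + 1.0)

    rows = []
    for g in genes:
        i = idx[g]
        means = {t: logv[i, cols[t]].mean() for t in tissues}
        center = np.mean(list(means.values()))
        for t in tissues:
            rows.append({"gene_id": g, "tissue": t,
                         "mean_log": means[t], "norm_log": means[t] - center})
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "mean_log", "norm_log"])


# ---------------------------------------------------------------------------
# DEG sets


def pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student t-test. Returns (t, df, p).

    Degenerate inputs: zero pooled variance with equal means -> p = 1 (no
    call); zero pooled variance with unequal means -> the smallest
    representable p with an infinite-signed t.
    """
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    if n1 < 2 or n2 < 2:
        raise ConfigError("t-test needs >= 2 samples per group")
    d = x.mean() - y.mean()
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    sp2 = ss / df
    if sp2 == 0.0:
        if d == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, d), df, _TINY_P
    t = d / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, min(p, 1.0) if p > 0 else _TINY_P


@dataclass
class DegSetCollection:
    """Per-tissue up/down/two-sided DEG sets plus the full statistics table."""

    stats: pd.DataFrame  # gene_id, tissue, t, df, lfc, p, adj_p
    alpha: float
    lfc_min: float
    up: dict[str, frozenset[str]] = field(default_factory=dict)
    down: dict[str, frozenset[str]] = field(default_factory=dict)
    twoside: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        return list(self.up)


def build_deg_sets(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    deg_alpha: float = 0.05,
    deg_lfc: float = 0.58,
    welch: bool = False,
    bonferroni_scope: str = "global",
) -> DegSetCollection:
    """Tissue-specificity t-tests: per gene and tissue, the tissue's samples
    against all other samples pooled, on per-sample log2(RPKM+1).

    Bonferroni is applied over all (gene x tissue) tests performed
    (``bonferroni_scope='global'``, the conservative default) or within each
    tissue (``'per_tissue'``). Membership: adj_p < ``deg_alpha`` and
    |lfc| >= ``deg_lfc``; up/down split by the sign of the t statistic.
    """
    if bonferroni_scope not in ("global", "per_tissue"):
        raise ConfigError("bonferroni_scope must be 'global' or 'per_tissue'")
    genes = list(expr.genes) if genes is None else genes
    tissues = expr.tissues
    idx = {g: i for i, g in enumerate(expr.genes)}
    logv = np.log2(expr.values + 1.0)
    cols = {t: np.asarray(expr.sample_columns(t), dtype=int) for t in tissues}
    all_cols = np.arange(len(expr.samples))

    rows = []
    for t_lab in tissues:
        tc = cols[t_lab]
        oc = np.setdiff1d(all_cols, tc)
        if len(tc) < 2 or len(oc) < 2:
            raise ConfigError(f"tissue {t_lab!r} needs >= 2 samples on each side of the split")
        for g in genes:
            x = logv[idx[g], tc]
            y = logv[idx[g], oc]
            if welch:
                from scipy.stats import ttest_ind

                res = ttest_ind(x, y, equal_var=False)
                t_stat, p = float(res.statistic), float(res.pvalue)
                df = int(res.df) if hasattr(res, "df") else len(x) + len(y) - 2
            else:
                t_stat, df, p = pooled_t(x, y)
            rows.append({"gene_id": g, "tissue": t_lab, "t": t_stat, "df": df,
                         "lfc": x.mean() - y.mean(), "p": p})
    stats = pd.DataFrame(rows, columns=["gene_id", "tissue", "t", "df", "lfc", "p"])

    if bonferroni_scope == "global":
        stats["adj_p"] = np.minimum(stats["p"] * len(stats), 1.0)
    else:
        stats["adj_p"] = stats.groupby("tissue")["p"].transform(
            lambda s: np.minimum(s * len(s), 1.0))

    coll = DegSetCollection(stats=stats, alpha=deg_alpha, lfc_min=deg_lfc)
    member = (stats["adj_p"] < deg_alpha) & (stats["lfc"].abs() >= deg_lfc)
    for t_lab in tissues:
        sub = stats[(stats["tissue"] == t_lab) & member]
        coll.up[t_lab] = frozenset(sub.loc[sub["t"] > 0, "gene_id"])
        coll.down[t_lab] = frozenset(sub.loc[sub["t"] < 0, "gene_id"])
        coll.twoside[t_lab] = frozenset(sub["gene_id"])
    return coll


# ---------------------------------------------------------------------------
# hypergeometric enrichment


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k) for drawing n from a
    population of N containing K successes, summed in log space."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0

    def log_c(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    denom = log_c(N, n)
    terms = [log_c(K, i) + log_c(N - K, n - i) - denom
             for i in range(k, min(n, K) + 1)
             if n - i <= N - K]
    if not terms:
        return 0.0
    m = max(terms)
    p = math.exp(m) * sum(math.exp(t - m) for t in terms)
    return min(p, 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    source_label: str
    N: int
    K: int
    n: int
    k: int
    p: float
    adj_p: float
    overlap_genes: tuple[str, ...]


def _adjust(pvals: list[float], method: str) -> list[float]:
    if not pvals:
        return []
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ConfigError(f"unknown adjustment method {method!r}")
    return list(multipletests(pvals, method=key)[1])


def enrich_gene_sets(
    genes: set[str] | list[str],
    collections: list[GeneSetCollection],
    background: set[str],
    adjust: str = "bh",
    adjp_max: float = 0.05,
    min_overlap: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hypergeometric over-representation of ``genes`` in every set of every
    collection, against ``background``. Adjustment is applied per source
    (collection), never pooled. Returns (full table, filtered report with
    adj_p <= ``adjp_max`` and overlap k >= ``min_overlap``)."""
    if not background:
        raise ConfigError("empty enrichment background")
    input_all = set(genes)
    input_genes = input_all & background
    dropped = len(input_all) - len(input_genes)
    if dropped:
        log.info("%d input genes outside the background dropped from enrichment", dropped)
    N = len(background)
    n = len(input_genes)

    results: list[EnrichmentResult] = []
    for coll in collections:
        per_source: list[tuple[str, int, int, tuple[str, ...], float]] = []
        for name in sorted(coll.sets):
            members = coll.sets[name] & background
            K = len(members)
            if K == 0:
                continue
            overlap = tuple(sorted(input_genes & members))
            k = len(overlap)
            per_source.append((name, K, k, overlap, hypergeom_pvalue(k, K, n, N)))
        adj = _adjust([r[4] for r in per_source], adjust)
        for (name, K, k, overlap, p), ap in zip(per_source, adj):
            results.append(EnrichmentResult(name, coll.source_label, N, K, n, k,
                                            p, max(ap, p), overlap))

    full = pd.DataFrame(
        [{"source": r.source_label, "set_name": r.set_name, "N": r.N, "K": r.K,
          "n": r.n, "k": r.k, "p": r.p, "adj_p": r.adj_p,
          "overlap_genes": ";".join(r.overlap_genes)} for r in results],
        columns=["source", "set_name", "N", "K", "n", "k", "p", "adj_p", "overlap_genes"])
    report = full[(full["adj_p"] <= adjp_max) & (full["k"] >= min_overlap)].reset_index(drop=True)
    return full, report


def enrich_deg(
    genes: set[str] | list[str],
    deg: DegSetCollection,
    background: set[str],
    adjust: str = "bh",
    adjp_max: float = 0.05,
    min_overlap: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test the input genes against every tissue's up/down/two-sided DEG set.

    Each direction is its own source: adjustment runs within a direction
    across tissues. Empty DEG sets are skipped."""
    collections = []
    for direction, sets in (("DEG_up", deg.up), ("DEG_down", deg.down),
                            ("DEG_twoside", deg.twoside)):
        coll = GeneSetCollection(source_label=direction)
        for tissue, members in sets.items():
            if members:
                coll.sets[tissue] = frozenset(members)
        if coll.sets:
            collections.append(coll)
    return enrich_gene_sets(genes, collections, background, adjust=adjust,
                            adjp_max=adjp_max, min_overlap=min_overlap)
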