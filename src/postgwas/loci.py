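"""Characterization of genomic risk loci from GWAS summary statistics.

The clumping follows the PLINK convention: genome-wide significant SNPs
(p < 5e-8) are scanned in ascending p order and greedily selected if they are
independent (r-squared below the threshold) of everything already selected.
Two rounds are run — r2 < 0.6 yields *independent significant SNPs*, r2 < 0.1
over those yields *lead SNPs*. Candidate SNPs are every reference-panel
variant with r2 >= 0.6 to an independent significant SNP (including proxies
with no GWAS p-value), and LD blocks closer than 250 kb are merged into one
genomic risk locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .refdata import (
    ConfigError,
    LdStore,
    Parameters,
    PanelVariant,
    SumstatRecord,
    chrom_sort_key,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndSigSNP:
    snp: SumstatRecord
    rank: int
    forced: bool = False  # predefined lead supplied by the user


@dataclass(frozen=True)
class LeadSNP:
    snp: SumstatRecord
    member_ind_sig: tuple[str, ...]  # snp_ids of the IndSigSNPs it represents
    forced: bool = False


@dataclass(frozen=True)
class CandidateSNP:
    variant: PanelVariant
    p: float | None            # absent for non-GWAS-tagged proxies
    best_r2: float
    nearest_ind_sig: str

    @property
    def gwas_tagged(self) -> bool:
        return self.p is not None


@dataclass
class RiskLocus:
    locus_id: int
    chrom: str
    start: int
    end: int
    lead_snps: list[LeadSNP] = field(default_factory=list)
    ind_sig_snps: list[IndSigSNP] = field(default_factory=list)
    candidates: list[CandidateSNP] = field(default_factory=list)

    @property
    def top_snp(self) -> SumstatRecord:
        return min((i.snp for i in self.ind_sig_snps if i.snp.p is not None),
                   key=lambda s: (s.p, chrom_sort_key(s.chrom), s.pos, s.snp_id))

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)


def _order_key(rec: SumstatRecord):
    # ascending p; deterministic tie-break by genome position then id
    return (rec.p if rec.p is not None else float("inf"),
            chrom_sort_key(rec.chrom), rec.pos, rec.snp_id)


def select_independent_significant(
    sumstats: list[SumstatRecord],
    panel: dict[str, PanelVariant],
    ld: LdStore,
    params: Parameters,
    forced: list[SumstatRecord] | None = None,
) -> list[IndSigSNP]:
    """Greedy clump at r2 < ``params.r2_ind`` over genome-wide significant SNPs.

    ``forced`` records (predefined lead SNPs) are placed ahead of the greedy
    scan and always selected, regardless of significance.
    """
    if not panel:
        raise ConfigError("reference panel is empty")
    in_panel = [r for r in sumstats if r.snp_id in panel]
    dropped = len(sumstats) - len(in_panel)
    if dropped:
        log.info("%d GWAS SNPs absent from the reference panel excluded from LD steps", dropped)

    selected: list[IndSigSNP] = []
    forced_ids = set()
    for rec in forced or []:
        if rec.snp_id not in panel:
            raise ConfigError(f"predefined lead SNP {rec.snp_id!r} absent from the reference panel")
        if rec.p is None or rec.p >= params.p_sig:
            log.warning("predefined lead %s is not genome-wide significant (p=%s); forced anyway",
                        rec.snp_id, rec.p)
        selected.append(IndSigSNP(snp=rec, rank=len(selected), forced=True))
        forced_ids.add(rec.snp_id)

    significant = sorted((r for r in in_panel
                          if r.p < params.p_sig and r.snp_id not in forced_ids),
                         key=_order_key)
    for rec in significant:
        if all(ld.r2(rec.snp_id, s.snp.snp_id) < params.r2_ind for s in selected):
            selected.append(IndSigSNP(snp=rec, rank=len(selected)))
    return selected


def select_lead(
    ind_sig: list[IndSigSNP],
    ld: LdStore,
    params: Parameters,
) -> list[LeadSNP]:
    """Second greedy round at r2 < ``params.r2_lead`` over the independent
    significant SNPs; non-selected ones are assigned to the first selected lead
    they are in LD with."""
    forced = [i for i in ind_sig if i.forced]
    rest = sorted((i for i in ind_sig if not i.forced), key=lambda i: _order_key(i.snp))
    ordered = forced + rest

    leads: list[tuple[IndSigSNP, list[str]]] = []
    for cand in ordered:
        assigned = False
        for lead, members in leads:
            if cand.forced:
                break  # forced ind-sig SNPs are always their own lead
            if ld.r2(cand.snp.snp_id, lead.snp.snp_id) >= params.r2_lead:
                members.append(cand.snp.snp_id)
                assigned = True
                break
        if not assigned:
            leads.append((cand, [cand.snp.snp_id]))
    return [LeadSNP(snp=lead.snp, member_ind_sig=tuple(members), forced=lead.forced)
            for lead, members in leads]


def collect_candidates(
    ind_sig: list[IndSigSNP],
    panel: dict[str, PanelVariant],
    ld: LdStore,
    sumstats: list[SumstatRecord],
    params: Parameters,
) -> list[CandidateSNP]:
    """All panel variants with r2 >= ``params.r2_ind`` to at least one
    independent significant SNP, MAF-filtered; proxies missing from the GWAS
    input keep p = None. Each candidate records its best r2 and the
    independent significant SNP attaining it (ties broken by smaller p)."""
    p_of = {r.snp_id: r.p for r in sumstats}
    ind_by_id = {i.snp.snp_id: i for i in ind_sig}

    best: dict[str, tuple[float, str]] = {}

    def consider(snp_id: str, r2: float, ind_id: str) -> None:
        cur = best.get(snp_id)
        if cur is None or r2 > cur[0] + 1e-12:
            best[snp_id] = (r2, ind_id)
        elif abs(r2 - cur[0]) <= 1e-12 and cur[1] != ind_id:
            # tie on r2: keep the independent significant SNP with the smaller p
            cur_p = ind_by_id[cur[1]].snp.p
            new_p = ind_by_id[ind_id].snp.p
            if (new_p, ind_id) < (cur_p, cur[1]):
                best[snp_id] = (r2, ind_id)

    for i in ind_sig:
        sid = i.snp.snp_id
        consider(sid, 1.0, sid)  # self-LD
        for partner, r2 in ld.partners(sid).items():
            if r2 >= params.r2_ind and partner in panel:
                consider(partner, r2, sid)

    out: list[CandidateSNP] = []
    for snp_id, (r2, ind_id) in best.items():
        variant = panel.get(snp_id)
        if variant is None:
            continue
        # the MAF filter applies to candidates but never removes an IndSigSNP
        if snp_id not in ind_by_id and variant.maf < params.maf_min:
            continue
        out.append(CandidateSNP(variant=variant, p=p_of.get(snp_id),
                                best_r2=r2, nearest_ind_sig=ind_id))
    out.sort(key=lambda c: (chrom_sort_key(c.variant.chrom), c.variant.pos, c.variant.snp_id))
    return out


def define_loci(
    ind_sig: list[IndSigSNP],
    candidates: list[CandidateSNP],
    leads: list[LeadSNP],
    ld: LdStore,
    params: Parameters,
) -> list[RiskLocus]:
    """Merge per-IndSigSNP LD blocks into genomic risk loci.

    Each independent significant SNP's block spans the candidate SNPs in LD
    with it (r2 >= r2_ind); blocks on one chromosome merge transitively,
    left to right, while the gap between consecutive block edges is strictly
    less than ``merge_kb`` kilobases.
    """
    if not ind_sig:
        return []
    # block extent per independent significant SNP
    blocks: dict[str, tuple[str, int, int]] = {}
    for i in ind_sig:
        sid, chrom, pos = i.snp.snp_id, i.snp.chrom, i.snp.pos
        lo, hi = pos, pos
        for c in candidates:
            if c.variant.chrom == chrom and ld.r2(c.variant.snp_id, sid) >= params.r2_ind:
                lo, hi = min(lo, c.variant.pos), max(hi, c.variant.pos)
        blocks[sid] = (chrom, lo, hi)

    ordered = sorted(ind_sig, key=lambda i: (chrom_sort_key(blocks[i.snp.snp_id][0]),
                                             blocks[i.snp.snp_id][1],
                                             blocks[i.snp.snp_id][2]))
    merge_bp = params.merge_kb * 1000
    groups: list[list[IndSigSNP]] = []
    cur_chrom, cur_end = None, None
    for i in ordered:
        chrom, lo, hi = blocks[i.snp.snp_id]
        if groups and chrom == cur_chrom and (lo - cur_end) < merge_bp:
            groups[-1].append(i)
            cur_end = max(cur_end, hi)
        else:
            groups.append([i])
            cur_chrom, cur_end = chrom, hi
        cur_end = max(cur_end, hi)

    locus_of_ind: dict[str, int] = {}
    loci: list[RiskLocus] = []
    for members in groups:
        chrom = blocks[members[0].snp.snp_id][0]
        start = min(blocks[m.snp.snp_id][1] for m in members)
        end = max(blocks[m.snp.snp_id][2] for m in members)
        locus = RiskLocus(locus_id=len(loci) + 1, chrom=chrom, start=start, end=end,
                          ind_sig_snps=list(members))
        loci.append(locus)
        for m in members:
            locus_of_ind[m.snp.snp_id] = locus.locus_id

    # a candidate belongs to the locus of its nearest independent significant SNP
    for c in candidates:
        loci[locus_of_ind[c.nearest_ind_sig] - 1].candidates.append(c)
    for lead in leads:
        loci[locus_of_ind[lead.snp.snp_id] - 1].lead_snps.append(lead)
    return loci


def characterize(
    sumstats: list[SumstatRecord],
    panel: dict[str, PanelVariant],
    ld: LdStore,
    params: Parameters,
    predefined_leads: list[str] | None = None,
    regions: list[tuple[str, int, int]] | None = None,
):
    """Run the full locus characterization; returns (ind_sig, leads, candidates, loci).

    ``predefined_leads`` are snp_ids forced into the selection (they must exist
    in the panel; a p-value is taken from the GWAS input when present).
    ``regions`` restricts all downstream annotation to the given 1-based
    inclusive intervals: significant SNPs and candidates outside them are
    discarded before loci are formed.
    """
    def in_regions(chrom: str, pos: int) -> bool:
        if regions is None:
            return True
        return any(c == chrom and s <= pos <= e for c, s, e in regions)

    working = [r for r in sumstats if in_regions(r.chrom, r.pos)]

    forced: list[SumstatRecord] = []
    if predefined_leads:
        by_id = {r.snp_id: r for r in sumstats}
        for sid in predefined_leads:
            if sid in by_id:
                forced.append(by_id[sid])
            elif sid in panel:
                v = panel[sid]
                forced.append(SumstatRecord(sid, v.chrom, v.pos, v.alt_allele,
                                            v.ref_allele, p=1.0))
                log.warning("predefined lead %s has no GWAS p-value; forced with p=1", sid)
            else:
                raise ConfigError(f"predefined lead SNP {sid!r} absent from the reference panel")
        forced = [f for f in forced if in_regions(f.chrom, f.pos)]

    ind_sig = select_independent_significant(working, panel, ld, params, forced=forced)
    if not ind_sig:
        return [], [], [], []
    leads = select_lead(ind_sig, ld, params)
    candidates = collect_candidates(ind_sig, panel, ld, working, params)
    if regions is not None:
        candidates = [c for c in candidates if in_regions(c.variant.chrom, c.variant.pos)]
    loci = define_loci(ind_sig, candidates, leads, ld, params)
    return ind_sig, leads, candidates, loci
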