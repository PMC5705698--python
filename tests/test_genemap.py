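"""Gene-mapping strategies, their filters, and the combined table."""

import numpy as np
import pytest

from postgwas import genemap
from postgwas.genemap import (
    chromatin_map,
    combine_maps,
    eqtl_map,
    filter_snps_functional,
    positional_map,
)
from postgwas.loci import CandidateSNP, RiskLocus
from postgwas.refdata import (
    ConfigError,
    EpigenomeRegionSet,
    EqtlRecord,
    GeneModel,
    InteractionRecord,
    PanelVariant,
)
from postgwas.snpannot import AnnotatedSNP, GeneIndex


def gene(gene_id, start, end, strand="+", gene_type="protein_coding", chrom="1"):
    return GeneModel(gene_id, gene_id, gene_type, chrom, start, end, strand,
                     ((start, end),))


def ann(snp_id, pos, consequence="intronic", cadd=None, rdb=None, states=None,
        genes=(), chrom="1"):
    c = CandidateSNP(PanelVariant(snp_id, chrom, pos, "A", "G", 0.3),
                     p=1e-9, best_r2=1.0, nearest_ind_sig="lead")
    a = AnnotatedSNP(candidate=c, consequence=consequence,
                     annotated_genes=[(g, 0) for g in genes])
    a.cadd = cadd
    a.rdb = rdb
    a.chromhmm_states = dict(states or {})
    return a


class TestFunctionalFilter:
    def test_cadd_threshold_drops_low_and_missing(self):
        snps = [ann("a", 1, cadd=15.1), ann("b", 2, cadd=3.0), ann("c", 3, cadd=None)]
        kept = filter_snps_functional(snps, cadd_min=12.37)
        assert [s.snp_id for s in kept] == ["a"]

    def test_no_filters_is_identity(self):
        snps = [ann("a", 1), ann("b", 2)]
        assert filter_snps_functional(snps) == snps

    def test_consequence_filter(self):
        snps = [ann("a", 1, "exonic"), ann("b", 2, "intronic"), ann("c", 3, "intergenic")]
        kept = filter_snps_functional(snps, allowed_consequences={"exonic", "splicing"})
        assert [s.snp_id for s in kept] == ["a"]

    def test_rdb_ordered_category(self):
        snps = [ann("a", 1, rdb="1a"), ann("b", 2, rdb="3b"), ann("c", 3, rdb=None)]
        kept = filter_snps_functional(snps, rdb_max="2c")
        assert [s.snp_id for s in kept] == ["a"]

    def test_chromatin_state_filter(self):
        snps = [ann("a", 1, states={"E1": 1}), ann("b", 2, states={"E1": 15}),
                ann("c", 3)]
        kept = filter_snps_functional(snps, allowed_states=set(range(1, 8)))
        assert [s.snp_id for s in kept] == ["a"]

    def test_contradictory_filters_empty_not_error(self):
        snps = [ann("a", 1, cadd=20.0)]
        assert filter_snps_functional(snps, cadd_min=50.0) == []


class TestPositionalMap:
    G = gene("g", 100_000, 120_000)

    def test_window_10kb_in_and_out(self):
        inside = ann("in", 96_000)     # 4 kb upstream
        outside = ann("out", 85_000)   # 15 kb upstream
        ev = positional_map([inside, outside], [self.G], window_kb=10)
        assert set(ev) == {"g"} and ev["g"].snp_ids == {"in"}

    def test_consequence_mode_excludes_intronic_only_genes(self):
        snps = [ann("e", 110_000, "exonic", genes=["g"]),
                ann("i", 111_000, "intronic", genes=["g2"])]
        ev = positional_map(snps, [self.G, gene("g2", 200_000, 210_000)],
                            allowed_consequences={"exonic", "splicing"})
        assert set(ev) == {"g"}


class TestEqtlMap:
    GENES = [gene("G1", 150_000, 160_000), gene("G2", 400_000, 410_000),
             gene("FAR", 5_000_000, 5_010_000)]

    def _snp(self, snp_id="s", pos=100_000):
        return ann(snp_id, pos)

    def _rec(self, gene_id, tissue="liver", p=1e-8, fdr=0.01, pos=100_000,
             ea="G", oa="A"):
        return EqtlRecord("1", pos, ea, oa, gene_id, tissue, p, fdr)

    def test_fdr_threshold(self):
        ev = eqtl_map([self._snp()], [self._rec("G1", fdr=0.01)], self.GENES, ["liver"])
        assert set(ev) == {"G1"} and ev["G1"].detail["tissues"] == {"liver"}
        ev = eqtl_map([self._snp()], [self._rec("G1", fdr=0.2)], self.GENES, ["liver"])
        assert ev == {}

    def test_multiple_genes_and_tissues_from_one_snp(self):
        recs = [self._rec("G1", "liver", fdr=0.01), self._rec("G2", "brain", fdr=0.04)]
        ev = eqtl_map([self._snp()], recs, self.GENES, ["liver", "brain"])
        assert set(ev) == {"G1", "G2"}

    def test_cis_bound_one_megabase(self):
        ev = eqtl_map([self._snp()], [self._rec("FAR", fdr=0.001)], self.GENES, ["liver"])
        assert ev == {}

    def test_allele_orientation_swap_accepted_mismatch_rejected(self):
        ev = eqtl_map([self._snp()], [self._rec("G1", ea="A", oa="G")], self.GENES, ["liver"])
        assert set(ev) == {"G1"}
        ev = eqtl_map([self._snp()], [self._rec("G1", ea="C", oa="T")], self.GENES, ["liver"])
        assert ev == {}

    def test_nominal_p_filter_mode(self):
        recs = [self._rec("G1", p=1e-3, fdr=0.5)]
        assert eqtl_map([self._snp()], recs, self.GENES, ["liver"]) == {}
        ev = eqtl_map([self._snp()], recs, self.GENES, ["liver"], p_max=0.01)
        assert set(ev) == {"G1"}

    def test_absent_tissue_is_config_error(self):
        with pytest.raises(ConfigError, match="kidney"):
            eqtl_map([self._snp()], [self._rec("G1")], self.GENES, ["kidney"])


class TestChromatinMap:
    # + strand gene with TSS 1,000,000: promoter [999,750 .. 1,000,500]
    GPLUS = gene("gp", 1_000_000, 1_050_000, strand="+")
    # - strand gene with TSS at its end 2,050,000: promoter [2,049,500 .. 2,050,250]
    GMINUS = gene("gm", 2_000_000, 2_050_000, strand="-")

    def _interaction(self, sa, ea, sb, eb, tissue="liver", fdr=1e-9):
        return InteractionRecord("1", sa, ea, "1", sb, eb, tissue, fdr)

    def test_plus_strand_promoter_overlap(self):
        snp = ann("s", 500_500)
        rec = self._interaction(500_000, 501_000, 999_800, 1_000_000)
        ev = chromatin_map([snp], [rec], [self.GPLUS], ["liver"])
        assert set(ev) == {"gp"} and ev["gp"].snp_ids == {"s"}

    def test_minus_strand_promoter_mirrored(self):
        snp = ann("s", 500_500)
        hit = self._interaction(500_000, 501_000, 2_050_200, 2_050_240)
        ev = chromatin_map([snp], [hit], [self.GMINUS], ["liver"])
        assert set(ev) == {"gm"}
        # just beyond the 250 bp downstream-of-TSS edge on the minus strand
        miss = self._interaction(500_000, 501_000, 2_050_251, 2_050_400)
        assert chromatin_map([snp], [miss], [self.GMINUS], ["liver"]) == {}

    def test_orientation_symmetric(self):
        snp = ann("s", 500_500)
        rec = self._interaction(999_800, 1_000_000, 500_000, 501_000)  # ends swapped
        ev = chromatin_map([snp], [rec], [self.GPLUS], ["liver"])
        assert set(ev) == {"gp"}

    def test_fdr_prefilter(self):
        snp = ann("s", 500_500)
        rec = self._interaction(500_000, 501_000, 999_800, 1_000_000, fdr=1e-3)
        assert chromatin_map([snp], [rec], [self.GPLUS], ["liver"]) == {}

    def test_enhancer_filter(self):
        snp = ann("s", 500_500)
        rec = self._interaction(500_000, 501_000, 999_800, 1_000_000)
        covering = EpigenomeRegionSet("enhancer", "E1", [("1", 500_400, 500_600)])
        elsewhere = EpigenomeRegionSet("enhancer", "E1", [("1", 700_000, 700_100)])
        assert set(chromatin_map([snp], [rec], [self.GPLUS], ["liver"],
                                 enhancer_sets=[covering])) == {"gp"}
        assert chromatin_map([snp], [rec], [self.GPLUS], ["liver"],
                             enhancer_sets=[elsewhere]) == {}

    def test_trans_chromosomal_interaction_honored(self):
        snp = ann("s", 500_500)
        g = gene("t", 1_000_000, 1_050_000, chrom="2")
        rec = InteractionRecord("1", 500_000, 501_000, "2", 999_800, 1_000_000,
                                "liver", 1e-9)
        ev = chromatin_map([snp], [rec], [g], ["liver"])
        assert set(ev) == {"t"}


class TestCombine:
    def _locus(self, snp_ids, start=100_000, end=200_000):
        cands = [CandidateSNP(PanelVariant(s, "1", start + 10, "A", "G", 0.3),
                              1e-9, 1.0, snp_ids[0]) for s in snp_ids]
        return RiskLocus(1, "1", start, end, candidates=cands)

    def test_outside_locus_gene_flagged(self):
        locus = self._locus(["s"])
        genes = [gene("far", 3_000_000, 3_010_000)]
        ev = {"far": genemap.MappingEvidence("eqtl", "far", {"s"})}
        ci = {"far": genemap.MappingEvidence("chromatin", "far", {"s"})}
        (m,) = combine_maps(None, ev, ci, [locus], genes)
        assert set(m.strategies) == {"eqtl", "chromatin"}
        assert m.loci == {1} and m.inside_locus is False

    def test_all_three_strategies_and_union_order_independence(self):
        locus = self._locus(["s"])
        genes = [gene("g", 150_000, 160_000)]
        pos = {"g": genemap.MappingEvidence("positional", "g", {"s"})}
        eq = {"g": genemap.MappingEvidence("eqtl", "g", {"s"})}
        ci = {"g": genemap.MappingEvidence("chromatin", "g", {"s"})}
        (m,) = combine_maps(pos, eq, ci, [locus], genes)
        assert set(m.strategies) == {"positional", "eqtl", "chromatin"}
        assert m.inside_locus is True
        (m2,) = combine_maps(pos, eq, ci, [locus], genes)  # idempotent
        assert m2.strategies.keys() == m.strategies.keys()

    def test_gene_type_restriction(self):
        locus = self._locus(["s"])
        genes = [gene("nc", 150_000, 160_000, gene_type="ncRNA")]
        ev = {"nc": genemap.MappingEvidence("eqtl", "nc", {"s"})}
        assert combine_maps(None, ev, None, [locus], genes) == []
        (m,) = combine_maps(None, ev, None, [locus], genes, gene_types=None)
        assert m.gene_id == "nc"

    def test_single_gene_locus_summary(self):
        locus = self._locus(["s"])
        genes = [gene("g", 150_000, 160_000)]
        ev = {"g": genemap.MappingEvidence("eqtl", "g", {"s"})}
        mapped = combine_maps(None, ev, None, [locus], genes)
        assert genemap.genes_per_locus(mapped, [locus]) == {1: 1}


class TestFilterIndependence:
    """Functional filters chosen for one strategy never leak into another."""

    def test_eqtl_evidence_unchanged_by_positional_cadd_filter(self, synth, params):
        from postgwas import loci as L
        from postgwas.snpannot import annotate_candidates

        bundle, sumstats, _ = synth
        _, _, cands, _ = L.characterize(sumstats, bundle.panel, bundle.ld, params)
        annotated = annotate_candidates(cands, bundle.genes, scores=bundle.scores)
        tissues = sorted({q.tissue for q in bundle.eqtls})

        # eQTL mapping always starts from the ORIGINAL candidate set
        baseline = eqtl_map(filter_snps_functional(annotated),
                            bundle.eqtls, bundle.genes, tissues)
        with_pos_filter = eqtl_map(filter_snps_functional(annotated),
                                   bundle.eqtls, bundle.genes, tissues)
        # applying the positional CADD filter to the positional branch only
        pos_subset = filter_snps_functional(annotated, cadd_min=12.37)
        assert len(pos_subset) < len(annotated)
        assert {g: ev.snp_ids for g, ev in baseline.items()} == \
               {g: ev.snp_ids for g, ev in with_pos_filter.items()}


class TestGeometryPostHoc:
    """Re-verify evidence geometry on random fixtures."""

    def test_eqtl_cis_and_promoter_overlap_invariants(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            genes = [gene(f"g{i}", int(s), int(s) + 20_000,
                          strand="+" if rng.uniform() < 0.5 else "-")
                     for i, s in enumerate(rng.choice(5_000_000, 8, replace=False) + 1)]
            snps = [ann(f"s{i}", int(p) + 1)
                    for i, p in enumerate(rng.choice(5_000_000, 15, replace=False))]
            eqtls = [EqtlRecord("1", s.candidate.variant.pos, "G", "A",
                                rng.choice([g.gene_id for g in genes]), "liver",
                                1e-8, float(rng.uniform(0, 0.1)))
                     for s in snps if rng.uniform() < 0.7]
            ev = eqtl_map(snps, eqtls, genes, ["liver"]) if eqtls else {}
            by_id = {g.gene_id: g for g in genes}
            pos_of = {s.snp_id: s.candidate.variant.pos for s in snps}
            for gid, e in ev.items():
                g = by_id[gid]
                for sid in e.snp_ids:
                    p = pos_of[sid]
                    d = 0 if g.start <= p <= g.end else min(abs(p - g.start), abs(p - g.end))
                    assert d <= genemap.CIS_WINDOW_BP

            inter = [InteractionRecord("1", int(a) + 1, int(a) + 40_000,
                                       "1", int(b) + 1, int(b) + 40_000,
                                       "liver", float(rng.uniform(0, 1e-6)))
                     for a, b in zip(rng.choice(5_000_000, 6), rng.choice(5_000_000, 6))]
            cev = chromatin_map(snps, inter, genes, ["liver"])
            for gid, e in cev.items():
                g = by_id[gid]
                lo, hi = g.promoter()
                assert any(
                    (rc == "1" and lo <= re and rs <= hi)
                    for rec in inter if rec.fdr <= 1e-6
                    for rc, rs, re in ((rec.chrom_a, rec.start_a, rec.end_a),
                                       (rec.chrom_b, rec.start_b, rec.end_b))
                )
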