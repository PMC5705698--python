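# Methods

This note documents the models and procedures implemented in `postgwas`, the
parameters that matter, the numerical choices, what the synthetic fixtures
emulate, and the known limitations.

## Locus characterization

Clumping is the PLINK-style greedy procedure over a pre-computed sparse
pairwise-r² table. Variants with p < `p_sig` (default 5×10⁻⁸) are scanned in
ascending p; a variant is selected iff its r² with *every already selected*
variant is below `r2_ind` (0.6). A second pass over the selected set at
`r2_lead` (0.1) yields lead SNPs, with each non-lead assigned to the first
selected lead it is correlated with. Ties in p are broken deterministically
by (chromosome, position, SNP id), so repeated runs are identical. Greedy
selection against the already-selected set — rather than a maximum
independent set — is the field convention and is what the bundled
first-principles oracle re-derives.

The LD table is assumed pre-filtered (stored pairs have r² ≥ 0.05 and
separation ≤ 1 Mb); an absent pair is treated as r² = 0 and self-LD is 1.
GWAS variants missing from the reference panel carry no LD information and
are excluded from clumping with a logged count. Candidate SNPs are the panel
variants with r² ≥ `r2_ind` to ≥ 1 independent significant SNP; proxies
absent from the GWAS input are kept with no p-value and flagged. The MAF
filter (`maf_min`, 0.01) applies to candidates only and never removes an
independent significant SNP. Per independent significant SNP, the LD block
spans its candidates' positions; blocks on one chromosome merge transitively
left-to-right while the edge gap is *strictly* less than `merge_kb` (250) —
a gap of exactly 250 kb keeps two loci. Locus boundaries come from candidate
positions, not gene spans.

User-supplied predefined lead SNPs are forced into both selection rounds
ahead of the greedy scan (they must exist in the panel; a warning is logged
when they are not genome-wide significant or absent from the GWAS input, but
they are forced regardless, matching the published use of manually submitted
leads). Predefined regions restrict significant SNPs and candidates before
loci are formed. A candidate in LD with independent significant SNPs of two
unmerged loci is assigned once, to the locus of the SNP attaining its best
r² (ties broken toward the smaller p).

## Consequence classification

The classifier is positional: precedence splicing > exonic > UTR5/UTR3 >
ncRNA_exonic > intronic > ncRNA_intronic > upstream > downstream >
intergenic. Splicing means within `splice_bp` (2) of an exon–intron boundary
on the intron side of a protein-coding gene; UTR calls require CDS bounds
and fall back to exonic without them; up-/downstream use a strand-aware
`flank_bp` (1000); intergenic SNPs carry their two closest flanking genes
with distances (one at chromosome ends). When a SNP overlaps several genes,
all are recorded and the highest-precedence consequence wins. Codon-level
sub-classes (nonsynonymous, stopgain) are out of scope — an external
per-variant consequence table can override the classifier, and "deleterious
coding" filtering is expressed as consequence ∈ {exonic, splicing} with
CADD ≥ 12.37. Score annotation is a left join: CADD by (chrom, pos, alleles)
accepting the swapped allele orientation but never strand flips, RegulomeDB
by position, chromatin state by 200-bp bin per selected epigenome; missing
entries stay absent. Catalog matching is exact on (chrom, pos).

## Gene mapping

Each strategy filters the *original* candidate set with its own functional
filter (CADD minimum, RegulomeDB category ≤ threshold in the ordered 1a…7
vocabulary, allowed chromatin states, allowed consequences; a SNP missing a
required score fails that filter). Filters never leak across strategies.

- *Positional*: window mode maps a SNP to every gene whose span padded by
  `pos_window_kb` (10) contains it; consequence mode maps a SNP to its
  annotated genes iff its consequence is selected.
- *eQTL*: join on position and alleles (exact or swapped), keep records with
  source-provided FDR ≤ `eqtl_fdr_max` (0.05) or, when nominal filtering is
  chosen, p ≤ `eqtl_p_max`; the 1 Mb cis bound is enforced against the gene
  body. FDR values are used verbatim, never recomputed.
- *Chromatin interaction*: interactions pre-filtered at FDR ≤ `ci_fdr_max`
  (10⁻⁶); a SNP overlapping either end maps every gene whose strand-aware
  promoter ([TSS−250, TSS+500] on +, mirrored on −, 1-based inclusive,
  overlap = ≥ 1 shared base) overlaps the other end. Both orientations are
  tested; promoter–promoter configurations are kept and flagged.
  Trans-chromosomal records are honored (no distance bound). Optional
  epigenome filters: the SNP end must fall in a predicted enhancer; the gene
  promoter must overlap a predicted promoter region.

The combined table is a set union (idempotent, order-independent) restricted
by default to protein-coding genes, with pLI/ncRVIS joined, locus
attribution through each supporting SNP's locus, an `inside_locus` flag from
gene-span/locus-span overlap, and per-locus mapped-gene counts (the
single-gene-locus summary).

## Expression, DEG sets, enrichment

Expressed genes have mean raw RPKM ≥ `expr_min_rpkm` (1) in ≥ 1 tissue
(boundary inclusive). Heatmap-style summaries per gene×tissue: `mean_log` =
mean over tissue samples of log₂(min(RPKM, `winsor_cap`)+1) with
`winsor_cap` = 50; `norm_log` re-centers `mean_log` to zero mean across
tissues within the gene (winsorization applies to these summaries only).

DEG tests are two-sided pooled-variance Student t-tests on per-sample
log₂(RPKM+1), one tissue's samples against all other samples pooled
(df = n₁+n₂−2); Welch is available behind a flag. Since the within-gene
centering subtracts a per-gene constant from every sample, running the test
on centered or raw log values is mathematically identical; the
implementation uses the raw log scale, and winsorization is not applied here.
Bonferroni runs over all (gene × tissue) tests performed — the conservative
scope; per-tissue correction is available as a parameter. Membership:
adjusted p < `deg_alpha` (0.05) and |lfc| ≥ `deg_lfc` (0.58 ≈ log₂ 1.5),
with up/down split by the sign of t and the two-sided set ignoring sign.
Degenerate inputs: zero pooled variance with equal means gives p = 1 (no
call); with unequal means the smallest representable double stands in for
p → 0 and the t statistic is signed infinity.

Enrichment is the upper-tail hypergeometric probability, summed in log space
via log-gamma binomial coefficients for stability (exact to ~10⁻¹⁵ against
rational enumeration at small N). Inputs and sets are intersected with the
background before N, K, n, k are computed; genes outside the background are
dropped with a logged count. Benjamini–Hochberg (default; Bonferroni
available) is applied within each data source independently — identical raw
p-values in different sources can receive different adjusted values. The
report keeps rows with adjusted p ≤ `enrich_adjp` (0.05) and overlap
k ≥ `enrich_min_overlap` (2); consequently a set with a single background
member can never be reported. The full unfiltered table is always written
alongside. DEG enrichment reuses the same machinery with one source per
direction (up/down/two-sided) across tissues; empty sets are skipped.

## Synthetic fixtures

The generator plants `n_loci` association blocks on one synthetic chromosome
(multi-chromosome layouts were considered and rejected to keep fixtures
small; positions are far below real chromosome lengths but the code is
agnostic). Within a block of 21 SNPs spaced 2 kb apart, r² decays linearly,
r² = max(0, 0.95 − d·rate) with rate 0.95/50 kb, so the clumping answer is
computable by construction: only SNPs with r² > 0.6 to the planted causal
SNP can reach genome-wide significance, giving exactly one independent
significant SNP per block. Blocks are ≥ 1 Mb apart with zero cross-block LD.
Each locus carries one coding-target gene containing the causal SNP in an
exon (CADD drawn from 15–30, above the 12.37 threshold; neighbors below 5),
one eQTL-target gene 300 kb away with a sub-threshold-FDR record on a
non-causal candidate (plus a distractor record with FDR in 0.2–0.9), one
interaction-target gene 600 kb away whose promoter sits in the distal end of
a significant interaction (plus a non-significant distractor interaction),
and eight evidence-free distractor genes. Expression is per-sample
log₂-normal (μ = 2, σ = 0.5); each locus's coding target is shifted by the
planted lfc (2.0) in one tissue; RPKM = max(2^x − 1, 0). Defaults: 4
tissues × 10 samples, 100 unlinked null SNPs with uniform p-values floored
at 10⁻⁶ so no null draw fakes a hit. All randomness flows from a single
integer seed through one generator per stage, so outputs are byte-identical
across runs.

What the fixtures do **not** emulate: coalescent LD structure, allele
frequency/effect-size coupling, polygenic backgrounds, winner's curse,
overlapping genes at realistic density, or real eQTL/Hi-C noise. Passing the
planted-recovery tests demonstrates that the *rules* are implemented
correctly, not that the defaults are optimal on real data.

## Numerical and design choices

- Internal coordinates are 1-based inclusive everywhere; BED/BEDPE are
  converted at the boundary (an exact bijection, property-tested).
  Chromosome labels are normalized by stripping a leading `chr`.
- Interval queries use interval trees; overlap is closed-interval, ≥ 1 base.
- The expression reader uses the round-trip float parser so written matrices
  re-read bit-exactly.
- Problem sizes in the verification suite — 1,000 random LD matrices (≤ 12
  significant SNPs), 100 seeds per planted-recovery condition, exhaustive
  hypergeometric enumeration to N = 12, 1,000 t-test draws, 100 geometry
  fixtures — are desk-scale choices that keep the whole suite under ten
  seconds while exercising every rule and boundary.
- The MAGMA gene-based step is an optional subprocess adapter: configured
  binary absent → stage skipped with a notice, never an error.

## Limitations

- No codon-aware consequence prediction, transcript-level annotation, or
  indel handling (SNVs only).
- No conditional/joint analysis, fine-mapping, TWAS imputation or
  colocalization; eQTL and interaction significance is taken from the source
  tables as published.
- No genotype ingestion or on-the-fly r² computation; the LD table is an
  input contract.
- Headline counts from the published BMI/CD/SCZ applications require the
  full external resources (1000G EUR LD, GTEx v6, GSE87112 Hi-C, complete
  summary statistics) and cannot be validated at desk scale; the presets in
  `presets/` encode those parameter settings for users with the data.
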