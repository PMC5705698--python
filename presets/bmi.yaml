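# Parameter preset for the body-mass-index application: positional mapping of
# deleterious coding SNPs (exonic/splicing, CADD >= 12.37), eQTL mapping at
# source FDR <= 0.05 across 44 tissues, chromatin-interaction mapping at
# FDR < 1e-6 across 14 tissue types. Supply your own input paths under
# `paths:`/`gmt:` (summary statistics, LD panel, gene models, eQTL and Hi-C
# tables); indels should be excluded upstream. Only protein-coding genes are
# mapped.
positional_mode: consequence
positional_consequences: [exonic, splicing]
pos_filter:
  cadd_min: 12.37
params:
  p_sig: 5.0e-8
  r2_ind: 0.6
  r2_lead: 0.1
  merge_kb: 250
  maf_min: 0.01
  eqtl_fdr_max: 0.05
  ci_fdr_max: 1.0e-6
paths: {}
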