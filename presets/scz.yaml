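# Parameter preset for the schizophrenia application: brain eQTL tissues,
# Hi-C from hippocampus and prefrontal cortex. The published analysis
# excluded the extended MHC region (chr6:25-34 Mb), chromosome X and indels
# (pass an intervals file via `--regions` to restrict annotation), and
# force-submitted the reported non-indel lead SNPs (`--predefined-leads`).
positional_mode: consequence
positional_consequences: [exonic, splicing]
pos_filter:
  cadd_min: 12.37
ci_tissues:
  - Hippocampus
  - Dorsolateral_Prefrontal_Cortex
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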