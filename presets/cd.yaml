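# Parameter preset for the Crohn's-disease application: same thresholds as
# the BMI preset, eQTLs restricted to digestive tissues + whole blood, Hi-C
# from liver and small bowel. The published analysis excluded the MHC region
# and indels upstream, and force-submitted the originally reported lead SNPs
# (use `--predefined-leads` with your list). Supply input paths under `paths:`.
positional_mode: consequence
positional_consequences: [exonic, splicing]
pos_filter:
  cadd_min: 12.37
eqtl_tissues:
  - Small_Intestine
  - Colon_Sigmoid
  - Colon_Transverse
  - Stomach
  - Whole_Blood
ci_tissues:
  - Liver
  - Small_Bowel
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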