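# Full-pipeline configuration: simulate the study-scale breeding design
# with a weak female centromeric drive, then count, test and report.
#
#   meiodrive run --config examples/pipeline_config.yaml --out scratch/run1 --seed 1
seed: 1
simulate:
  drive:
    - {chromosome: all, parent_sex: F, stage: MI_centromere, d: 0.475}
simulate_sites: true
stats:
  p0: auto             # pooled male rate from a marker random-intercept GLMM
  background_mode: glmm
counting:
  ambiguous_policy: exclude
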