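# Demo pipeline: simulate the default vineyard and run the full analysis.
# Jackknife refit count kept moderate so the demo completes in minutes on
# one CPU.

input:
  simulate:
    seed: 1

window: {lower: 400, upper: 2400, step: 1}
outlier_factor: 2
transforms: default

splits:
  random: 11
  cultivar: 12

plsr:
  a_max: 15
  scale: false

jackknife:
  enabled: true
  B: 200
  leave_frac: 0.2
  seed: 13

output_dir: vitespec_out
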