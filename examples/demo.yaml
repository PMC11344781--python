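# Synthetic end-to-end demo: 200 planted origins on two chromosomes.
seed: 11
outdir: exorigin_demo
generator:
  n_origins: 200
  n_chroms: 2
depths:
  ORC_G1: 150000
  ORC_G2: 150000
  ORC_S: 150000
  MCM_G1: 150000
stages:
  simulate: true
  footprint: true
  occupancy: true
  motif: true
  architecture: true
  shape: true
  deform: true
params:
  b2_window: 150
  p_threshold: 0.0001
  spectrum_permutations: 1000
  baseline_n: 500
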