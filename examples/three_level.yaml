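# Three-level population: 5% close-minded, 75% moderate, 20% open-minded.
population:
  n: 200
  levels:
    - {epsilon: 0.01, fraction: 0.05}
    - {epsilon: 0.2, fraction: 0.75}
    - {epsilon: 0.45, fraction: 0.20}
  initial: {kind: uniform, interval: [0.0, 1.0]}
  seed: 1
dynamics:
  t_max: 10000
  tol: 1.0e-8
  record_mode: 10        # keep every 10th profile
analysis:
  gap: 1.0e-4
  fractions: [0.01, 0.02, 0.05, 0.10, 0.30]
  sizes: [100, 200, 300, 500, 800, 1000]
  replicates: 20
output:
  directory: hkopinion-out
  plots: false
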