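# Fibrosis study: moduli vs CPA for two collagen stiffnesses.
# Run: lobule-homog sweep --config examples/fibrosis_sweep.yaml --out out/fibrosis
experiment: fibrosis
cpa_targets: [0.01, 0.05, 0.10, 0.15, 0.20]
collagen_G: [60000.0, 120000.0]
frequencies: [100.0]
patterns: [pattern1, pattern2]
n_realizations: 25
base_seed: 0
mesh: [40, 80]
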