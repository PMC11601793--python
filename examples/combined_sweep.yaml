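# Combined steatosis + fibrosis maps at the two elastography frequencies,
# power-law matrix. CPA stays <= 10% (no bridging), fat Pattern 1.
# Run: lobule-homog sweep --config examples/combined_sweep.yaml --out out/combined
experiment: combined
fat_targets: [0.0, 0.1, 0.2, 0.3]
cpa_targets: [0.02, 0.05, 0.08, 0.10]
collagen_G: [60000.0]
frequencies: [100.0, 300.0]
n_realizations: 10
base_seed: 0
mesh: [40, 80]
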