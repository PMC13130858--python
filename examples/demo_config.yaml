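# Demo: two harmonic diabats coupled to a 2-oscillator bath at the
# condensed-phase energy scale (environment self-energy ~ -4e4 kcal/mol).
# Desk-scale sampling: ~1 minute end to end.
system:
  diabat1: {type: harmonic, k: 100.0, r0: 0.0}
  diabat2: {type: harmonic, k: 100.0, r0: 1.0}
  n_bath: 2
  bath_k: [60.0, 80.0]
  bath_chain_kappa: 5.0
  g1: 3.0
  g2: -3.0
  uss_offset: -40000.0
  mass_r: 12.0
  mass_bath: 12.0
  friction: 40.0
  dt: 0.001

evb:
  delta_alpha: 3.0
  coupling: {form: constant, A: 8.0, b: 0.0}

sampling:
  n_windows: 21
  temperatures: [290.0, 295.0, 300.0, 305.0, 310.0]
  n_replicates: 6
  steps_per_window: 8000
  n_equil: 2000
  master_seed: 2026

analysis:
  n_bins: 40
  equil_fraction: 0.1
  coverage_threshold: 0.9
  min_count: 10
  estimator: delta
  reweight: false
  convergence_fractions: [0.25, 0.5, 0.75, 1.0]
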