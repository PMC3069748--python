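# Reference toy SAD problem: P21 crystal, 150 light atoms, 2 Se sites.
seed: 1
outdir: out
steps: [fa, detect, phase, dm, hand]
free_fraction: 0.05
experiment:
  kind: SAD
  source: simulate
  structure:
    cell: [34.0, 42.0, 38.0, 90.0, 90.0, 90.0]
    spacegroup: P21
    n_light: 150
  heavy:
    - {element: Se, count: 2, f_prime: -2.0, f_dprime: 4.0}
  channels:
    - {label: peak, f_prime: -2.0, f_dprime: 4.0}
  d_min: 2.2
  noise_frac: 0.05
params:
  detect: {n_trials: 5}
  phase: {refine_positions: true}
  dm: {n_cycles: 5, solvent_fraction: 0.45}
  hand: {n_cycles: 3}
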