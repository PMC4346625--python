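# Demo pipeline: synthetic chiral-like fibre, all five stages.
seed: 7
output_dir: fibremetrics_run
window_fraction: 0.25
generator:
  n_monomers: 12
  n_frames: 16
  stacking_sigma: 0.15
  dihedral_mix: [0.76, 0.19, 0.05]
  fold_factor: 0.58
  energy_spec:
    mean: -3.0
    sd: 1.0
    domains: [[5, 7, 2.5]]
hbond: {d_cut: 3.5, angle_cut: 120.0}
energy: {cutoff: 10.0, eps_in: 1.0, eps_out: 78.5}
saxs: {n_points: 100}
fret: {n_points: 300}
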