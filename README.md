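# fibremetrics

Multi-scale analysis of water-soluble supramolecular polymer fibres —
the kind built from C3-symmetric benzene-1,3,5-tricarboxamide (BTA)
monomers that stack into helical columns through threefold amide
hydrogen bonding and hydrophobic collapse.

The package is for researchers who characterise such fibres with
molecular simulation and scattering/fluorescence experiments and want
the quantitative layer between raw data and a results table:

* **Structural order** on stacked-fibre trajectories: intercore
  spacings and their radial distribution function g(r), amide-dihedral
  helicity classification (P / M / flipped), hydrogen-bond occupancy and
  >95% persistence, fibre length/thickness and contraction,
  solvent-accessible surface area, stable-domain detection.
* **Self-assembly energetics** (MM-GBSA style): gas-phase nonbonded
  terms, generalized Born polar solvation (Still's expression on
  Coulomb-field descreening radii), SASA-proportional nonpolar term, the
  per-monomer self-assembly energy ΔE = ⟨E_fibre⟩/N − ⟨E_monomer⟩, and
  its per-monomer / pairwise decomposition with a conservation identity.
* **SAXS**: the Pedersen–Schurtenberger flexible-cylinder (worm-like
  chain) model I(q) = scale·S_chain(q; L_c, L_k)·[2J₁(qr_cs)/qr_cs]² +
  bkg, weighted least-squares fitting with χ²/N and bound-hit
  diagnostics, plus a Debye-sum theoretical profile from bead models.
* **FRET exchange kinetics**: the mixing-assay ratio
  I_A/(I_D + I_A) and biexponential rise-to-plateau fitting
  F(t) = F_p − A_f·e^(−t/τ_f) − A_s·e^(−t/τ_s), plateau times and
  timescale fold changes.
* **Synthetic data**: generators for ideal and disordered 48-monomer
  stacks (3.4 Å spacing, −140° amide dihedrals, 16.3 nm repeat),
  hydrogen-bond occupancy matrices, per-monomer energy profiles with
  stable domains, flexible-cylinder scattering curves over
  q = 0.15–4.47 nm⁻¹ and biexponential FRET traces — all seeded,
  bit-reproducible and with recoverable ground truth, so every analysis
  stage is testable without external data.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

The arithmetic that links persistent hydrogen-bond counts to energies,
for three reference fibres (achiral, chiral, and a discordant-chirality
control), 48 monomers each:

```sh
$ fibremetrics demo --verify
     fibre  persistent_hbonds  hbs_per_bta  dE_HBs_kcal  dE_sol_kcal  sol_over_hbs  contraction_pct  flipped_dihedrals  flipped_pct  hb_increase_pct
   achiral                 39          1.6         -2.6        -39.5          15.2               56               23.0         16.0               44
    chiral                 56          2.3         -3.7        -38.9          10.5               42                7.0          5.0               44
discordant                 48          2.0         -3.2        -40.3          12.6               56                NaN          NaN               44
verification PASSED
```

Reading the achiral row: 39 persistent bonds over 48 monomers, doubled
because each monomer bonds to both stacking neighbours, give 1.6 bonds
per monomer; at −1.58 kcal/mol per aqueous H-bond that is −2.6 kcal/mol —
15.2 times smaller in magnitude than the −39.5 kcal/mol solvation term,
i.e. hydrophobicity dominates hydrogen bonding.  The chiral fibre keeps
44% more persistent bonds and contracts less (42% vs 56% from the
16.3 nm build), and only 5% of its 144 amide dihedrals flip to positive
angles versus 16% in the achiral fibre.

A library-level example — generate a disordered trajectory and measure
its helicity mixture back:

```python
from fibremetrics.synthetic_data import GeneratorConfig, build_ideal_fiber, perturb_trajectory
from fibremetrics.fiber_structure import helicity_fractions

cfg = GeneratorConfig(n_monomers=48, n_frames=20, stacking_sigma=0.15,
                      dihedral_mix=(0.76, 0.19, 0.05), fold_factor=0.58, seed=7)
topo, frame0 = build_ideal_fiber(cfg)          # 16.3 nm periodic repeat
traj = perturb_trajectory(topo, cfg)           # ~9.5 nm after folding
hel = helicity_fractions(traj, topo)
print(f"P {hel.fraction_p:.1f}%  M {hel.fraction_m:.1f}%  flipped {hel.fraction_flipped:.1f}%")
# P 76.1%  M 18.8%  flipped 5.1%
```

The full pipeline (simulate → structure → energy → SAXS fit → FRET fit)
runs from one YAML config:

```sh
fibremetrics run config.yaml     # writes CSV/JSON + manifest with config hash and seed
fibremetrics validate config.yaml
```

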