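# Methods

`fibremetrics` analyses one-dimensional supramolecular polymers built
from C3-symmetric monomers (benzene-1,3,5-tricarboxamide, BTA) that
stack into helical fibres through threefold amide hydrogen bonding and
hydrophobic collapse.  The package has two halves: analysis operations
(structure, energetics, scattering, exchange kinetics) and synthetic
generators that produce inputs with known ground truth so every
operation is testable end to end without simulation or beam-time data.

## Coarse fibre representation

A monomer is represented by one aromatic-core centroid bead, three amide
groups and three side-chain envelope beads.  Each amide carries the
dihedral quadruplet C_AR–C_AR–C(=O)–O (two ring carbons, carbonyl carbon
and oxygen) plus an N–H donor; the carbonyl oxygen doubles as the
hydrogen-bond acceptor.  Per atom the topology stores a partial charge
(e), 12-6 Lennard-Jones parameters (ε kcal/mol, σ Å) and an intrinsic
Born radius (Å).  The fibre axis is z, periodicity is minimum-image
along z only, and the periodic repeat length travels on each frame
(`box_z`, the CRYST1 c-axis in PDB output).

This resolution is deliberate: the analyses consume core positions,
amide dihedrals, donor/acceptor geometry and per-atom parameters, and
nothing else.  Full atomistics would add cost without adding anything
the operations could measure.

### The ideal build and its perturbations

The reference construction stacks `n_monomers = 48` cores at
`intercore_distance = 3.4 Å` with every amide dihedral at
`dihedral0 = −140°` (P-helicity) and an extended side-chain envelope of
diameter 6.8 nm, giving a periodic repeat of 48 × 0.34 nm = 16.3 nm.
These defaults are the study conditions of the reference system and are
not tuning knobs.  Fibre "length" is the periodic repeat n·d — the only
convention consistent with a fibre that is infinite through its periodic
images (the 47-gap convention would give 15.98 nm).

`perturb_trajectory` emulates a relaxed trajectory:

* core spacings drawn Normal(d, `stacking_sigma`), truncated positive;
* each amide assigned a helicity class from `dihedral_mix`
  (P/M/flipped fractions) per frame, with the angle drawn uniformly
  inside a window comfortably interior to its class
  (P: −170…−100°, M: −80…−10°, flipped: 10…170°), and the carbonyl
  oxygen re-placed by the natural-extension-reference-frame construction
  so the coordinates realise the drawn dihedral exactly;
* axial compression by `fold_factor` (equilibrated/initial length), a
  stand-in for hydrophobic folding — the analyses are insensitive to
  the folding pathway, only to the resulting length and disorder;
* donor N–H groups track the acceptor oxygen across their stacking
  interface (N 2.9 Å above it, H pointing at it), so the hydrogen-bond
  ladder survives the jitter.  Broken-bond statistics are generated
  separately (below) rather than geometrically.

All randomness flows from one integer seed; each generator reads its own
named substream (`np.random.default_rng([seed, stream_id])`) so
sub-generators are independently reproducible and bit-identical under
repetition.

### What the generators do not emulate

No explicit water, no force field, no thermostat — the trajectories have
the statistical structure the analyses assume (spacing jitter, dihedral
mixtures, compression), not the physics that produces it.  Passing tests
demonstrate that the analysis operations measure what they claim to
measure on data of known truth; they say nothing about force-field
accuracy, sampling convergence or the absolute energies of any real
fibre.

## Structural analyses

* **Intercore distances / g(r).**  Consecutive core-centroid distances
  including the wrap-around spacing (length n).  The radial distribution
  histograms all core–core distances with bins centred on multiples of
  the bin width (so an ideal spacing lands mid-bin), normalised by
  spherical-shell volume and mean density so an uncorrelated arrangement
  averages to 1.  For a z-periodic fibre the reference volume defaults
  to a cylinder of radius r_max and height box_z; any fixed convention
  is valid for peak-height comparisons provided it is applied to both
  curves, which `order_increase` (percent change of first-peak height,
  ties toward smaller r) enforces by requiring shared binning.
* **Helicity.**  Signed dihedrals in (−180°, 180°], IUPAC convention.
  Classes: P for angles ≤ −90°, M in (−90°, 0°], flipped positive; the
  −90° and 0° boundaries go to P and M respectively.  The M range is
  inferred as a negative-angle class — the only reading under which the
  reported three-way fractions close to 100%.  The mean dihedral is
  arithmetic over the analysis window by default; a circular mean is
  available because arithmetic means of angles near ±180° are
  ill-defined.
* **Hydrogen bonds.**  Geometric criterion: donor–acceptor heavy-atom
  distance < 3.5 Å and D–H···A angle > 120° (common trajectory-analysis
  defaults; both config-exposed, since the reference analysis tool's
  criteria are unstated).  Occupancy is the presence fraction over the
  analysis window; "persistent" means occupancy strictly above 0.95.
* **Analysis window.**  Equilibrium averages use a trailing fraction of
  frames, default the last 25% (mirroring a production run whose final
  quarter is representative).
* **Dimensions.**  Length = periodic repeat; thickness = twice the
  (5th, 95th) percentile of side-bead radial distance — a robust
  envelope, since a single thickness is ill-defined for a folded fibre.
* **SASA.**  Shrake–Rupley with a deterministic Fibonacci point set
  (default 960 points), probe 1.4 Å; per-atom areas sum to the total by
  construction.  Against the exact two-sphere spherical-cap formula the
  960-point estimate is within 2%.
* **Stable domains.**  Maximal runs of ≥ 5 consecutive monomers with
  per-monomer energy strictly below the fibre mean; optionally periodic
  across the boundary.  Under baseline noise the run boundary is not
  exactly identifiable by any below-mean rule, so exact-recovery claims
  hold for noise-free constructions and localisation claims for noisy
  ones.

## Energy engine

MM-GBSA-style bookkeeping in kcal/mol, Å, elementary charges
(Coulomb constant 332.0636 kcal·Å/(mol·e²)):

* **Gas phase:** pairwise Coulomb + 12-6 LJ (Lorentz–Berthelot), all
  intra-monomer pairs excluded (the coarse topology has no intra-monomer
  energetics in scope), hard 10 Å cutoff with no switching.  The engine
  targets decomposition bookkeeping, not dynamics, so truncated
  electrostatics are acceptable and documented.
* **Polar solvation:** Still's generalized Born expression with
  f_GB = sqrt(r² + R_iR_j·exp(−r²/4R_iR_j)), self terms included,
  interior/exterior dielectrics 1/78.5 (aqueous, 20 °C).  Effective
  radii are exact Coulomb-field pairwise-descreening integrals (the HCT
  closed form with unit screening factors): an isolated atom keeps its
  intrinsic radius, and for a non-overlapping pair the result equals
  direct quadrature of r⁻⁴ over the descreening sphere to machine
  precision.  Because pairwise descreening double-counts overlap volume,
  densely overlapping bead geometries can over-descreen; effective radii
  are therefore ceiling-clamped at 30 Å (the conventional buried-atom
  guard).  Single-ion energies reduce to the Born equation to < 1e−9
  relative.
* **Nonpolar solvation:** ΔE_NP = 0.00542·SASA + 0.92 (kcal/mol, SASA in
  Å²).
* **Self-assembly energy:** ΔE = ⟨E_fibre⟩/N − ⟨E_monomer⟩ — the energy
  gain for one monomer to sit in the fibre rather than be dissolved;
  negative is favourable.  Both ensembles must carry identical energy
  settings (enforced).
* **Decomposition:** ΔE_int(n,m) collects all gas pair terms and all GB
  cross terms between monomers n and m; intra-monomer GB (with self
  terms) and the per-monomer SASA share (plus b/N of the intercept) form
  the own-terms vector.  SASA is a per-atom quantity and is never split
  pairwise.  Conservation — ½·ΣΔE_int + Σown = E_gas + E_GB + E_NP — is
  an invariant tested to machine precision, and is how a sign/factor
  error in any cross term is caught.
* **Neighbour profile:** mean ΔE_int(n, n±k) for k = 1…N/2 with periodic
  indexing, plus the cumulative fraction used to judge where interaction
  with the fibre matrix saturates.
* **Hydrogen-bond bookkeeping:** persistent bonds per monomer are
  doubled (each monomer shares an interface with both neighbours), and
  multiplied by the typical aqueous peptide H-bond energy −1.58 kcal/mol.
  The reporting protocol for magnitude ratios rounds both operands to
  one decimal first and reports the ratio to one decimal — the
  convention of summary tables printed to one decimal — while ΔE_HBs
  itself is computed from the unrounded per-monomer count.  Both
  behaviours are fixed and covered by tests.
* **Histogram statistics:** mean/median/sd plus adjusted Fisher–Pearson
  skewness; near-zero skew indicates uniform disorder, negative skew a
  fibre with stable domains.

## SAXS: flexible cylinder model

The chain factor follows the Pedersen–Schurtenberger description of
semi-flexible self-avoiding chains ("method 3" with excluded volume):
below the crossover q_c = max(3.1/L_k, 1.9/R_g), an excluded-volume
chain function (Debye function blended by a tanh switch into the
three-term (qR_g)^(−1/ν) expansion, ν = 0.585, with the R_g expansion
factor α(n_b) and the local-stiffness correction scaled by
C(n_b)/n_b); above it, the local-rod form
a₁(qL_k)^(−p1) + a₂(qL_k)^(−p2) + π/(qL_c).  Instead of tabulated fit
coefficients, a₁ and a₂ are fixed by requiring continuity of value and
first derivative at q_c, which keeps the model smooth in both q and the
parameters.  Exponents (4.12, 4.42) apply for n_b = L_c/L_k ≥ 4 and
(5.36, 5.476) below.  The implementation is validated against the exact
orientation-averaged rigid-rod integral (within 2% over the instrument
q-range when L_k ≥ L_c), the −1 intermediate-q log-slope for L_c ≫ L_k,
and S(0) = 1.

The cross-section is a homogeneous circular cylinder [2J₁(qr_cs)/qr_cs]²
with optional Gaussian dispersity of r_cs averaged by 15-point
Gauss–Hermite quadrature (truncated at positive radius).
I(q) = scale · S_chain · S_cs + background.

Fitting minimises Σ((I−model)/σ)² with `scipy.optimize.least_squares`
(trf, bounds); points with σ = 0 get unit weight.  The Bessel zeros make
the objective multi-modal in r_cs, so a deterministic grid of starting
points around the initial guess (r_cs × {0.7, 1, 1.3}, L_k × {0.5, 1, 2})
is tried and the best optimum kept.  Reported: χ²/N (N = point count),
asymptotic-covariance standard errors, and a bound-hit diagnostic (a
contour length pinned at its bound means the data cannot resolve it —
expected when the contour exceeds the 2π/q_min window).  Uncertainties
on nearly flat directions (L_k in particular) are asymptotic and should
be read as ill-conditioning flags, not confidence intervals.

The Debye-sum profile I(q) = ΣΣ f_i f_j sinc(q r_ij) provides a
theoretical curve from bead coordinates with uniform form factors by
default; it applies no hydration shell or excluded-solvent term and is
an approximation to full solution-scattering predictors, not a
reproduction of them.

Units: q in 1/nm externally (instrument grid 0.15–4.47 nm⁻¹,
geometrically spaced, 150 points by default), SAXS lengths in nm,
structure coordinates in Å (converted once, internally).

## FRET exchange kinetics

The ratio is acceptor/(donor+acceptor) under donor excitation — bounded,
and invariant to common channel rescaling; acceptor/donor is exposed as
an option since the ratio definition varies between labs.  Exchange is
modelled as a rise to plateau with two decaying deficits,
F(t) = F_p − A_f·e^(−t/τ_f) − A_s·e^(−t/τ_s), canonically ordered
τ_f ≤ τ_s.  Fitting uses multi-start least squares over log-spaced
timescale pairs (log-parameterised τ, bounded non-negative amplitudes);
a constant series returns zero amplitudes with the plateau at the mean,
and a monoexponential input collapses to one near-zero amplitude.
`plateau_time` solves F(t) = F(0) + f·(F_p − F(0)) by bracketed root
finding (for a monoexponential at f = 0.95 this is −ln(0.05)·τ ≈ 3τ);
`compare_kinetics` reports per-component fold changes with first-order
error propagation (validated against Monte-Carlo resampling).

## Pipeline and provenance

`run_pipeline` executes simulate → structure → energy → saxs → fret from
one YAML config; every output embeds the SHA-256 config hash and the
seed, stage failures are recorded machine-readably (non-zero CLI exit)
without aborting later stages, and a rerun with the same config+seed is
byte-identical.  The energy stage decomposes a thinned set of
equilibrated frames (the bookkeeping is exact per frame, so a few frames
characterise a synthetic ensemble at a fraction of the O(N²_atoms) cost).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run synthetic problems sized
for a laptop: fibres of 4–48 monomers, trajectories of 2–500 frames,
150-point scattering grids with 20 fit replicates, 400-point FRET traces
with 20 replicates.  These sizes were chosen so each check exercises the
full code path with comfortable statistical margins.

## Known limitations

* Absolute self-assembly energies of real fibres are not reproducible
  here by construction: they require a full force field and long
  explicit-solvent sampling.  The engine guarantees bookkeeping
  identities and closed-form limits, not absolute magnitudes.
* GB radii use unit screening factors plus a ceiling clamp rather than
  element-specific screening; adequate for a coarse bead model, not for
  atomistic accuracy.
* The chain form factor's continuity-matched rod coefficients reproduce
  the published model family's behaviour but are not numerically
  identical to any specific tabulated implementation.
* Thickness and mean-dihedral conventions are stand-ins where the
  field's definitions are ambiguous (percentile envelope; arithmetic vs
  circular mean) and are flagged as such in the API.
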