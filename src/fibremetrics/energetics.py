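"""MM-GBSA-style self-assembly energy engine.

Gas-phase nonbonded terms (Coulomb + 12-6 Lennard-Jones), generalized
Born polar solvation (Still's pairwise expression on HCT
pairwise-descreening effective radii), a SASA-proportional nonpolar
term, the self-assembly energy

    dE = <per-monomer energy in the fibre> - <energy of the dissolved monomer>

and its per-monomer / pairwise decomposition, neighbour-interaction
profiles and hydrogen-bond energy bookkeeping.

Units: kcal/mol, Angstrom, elementary charges.  The Coulomb constant is
332.0636 kcal A / (mol e^2).  Negative energies are favourable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .topology import FiberFrame, FiberTopology, Trajectory, minimum_image_dz
from .fiber_structure import sasa as _sasa

COULOMB = 332.0636          # kcal A mol^-1 e^-2
NP_SLOPE = 0.00542          # g, kcal mol^-1 A^-2
NP_INTERCEPT = 0.92         # b, kcal mol^-1
E_HB_WATER = -1.58          # kcal mol^-1 per peptide-like H-bond in water


@dataclass(frozen=True)
class EnergySettings:
    """Everything that parameterises an energy evaluation.

    Two ensembles are only comparable when their settings are equal.
    """

    cutoff: float = 10.0         # A, hard truncation, no switching
    eps_in: float = 1.0
    eps_out: float = 78.5
    probe: float = 1.4           # A, SASA probe
    sasa_points: int = 960
    np_slope: float = NP_SLOPE
    np_intercept: float = NP_INTERCEPT


@dataclass
class EnergyBreakdown:
    e_gas: float
    e_gb: float
    e_np: float

    @property
    def e_sol(self) -> float:
        return self.e_gb + self.e_np

    @property
    def total(self) -> float:
        return self.e_gas + self.e_sol


# ---------------------------------------------------------------------------
# gas phase
# ---------------------------------------------------------------------------

def _pair_arrays(topology: FiberTopology):
    """Upper-triangle atom pairs excluding intra-monomer pairs."""
    n = topology.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    mono = topology.monomer_of_atom
    keep = mono[iu] != mono[ju]
    return iu[keep], ju[keep]


def energy_gas(
    frame: FiberFrame,
    topology: FiberTopology,
    cutoff: float = 10.0,
    return_pairs: bool = False,
):
    """Total gas-phase nonbonded energy.

    Pairwise Coulomb plus 12-6 LJ with Lorentz-Berthelot combining,
    excluding all intra-monomer pairs, hard-truncated at the cutoff with
    no switching, minimum image along z.  With ``return_pairs`` the
    (i, j, e_ele, e_vdw) arrays are returned for decomposition.
    """
    if np.any(np.isnan(topology.charges)):
        bad = int(np.flatnonzero(np.isnan(topology.charges))[0])
        raise ValueError(f"missing charge for atom {bad}")
    iu, ju = _pair_arrays(topology)
    delta = frame.coords[iu] - frame.coords[ju]
    delta[:, 2] = minimum_image_dz(delta[:, 2], frame.box_z)
    r = np.linalg.norm(delta, axis=1)
    mask = r < cutoff
    iu, ju, r = iu[mask], ju[mask], r[mask]
    q = topology.charges
    e_ele = COULOMB * q[iu] * q[ju] / r
    sig = 0.5 * (topology.lj_sigma[iu] + topology.lj_sigma[ju])
    eps = np.sqrt(topology.lj_epsilon[iu] * topology.lj_epsilon[ju])
    sr6 = (sig / r) ** 6
    e_vdw = 4.0 * eps * (sr6**2 - sr6)
    total = float(e_ele.sum() + e_vdw.sum())
    if return_pairs:
        return total, (iu, ju, e_ele, e_vdw)
    return total


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------

def born_radii(
    coords: np.ndarray, intrinsic: np.ndarray, r_max: float = 30.0
) -> np.ndarray:
    """HCT pairwise-descreening effective Born radii.

    The inverse effective radius of atom i is its inverse intrinsic
    radius minus the analytic integral of r^-4 over every other atom's
    sphere (the exact Coulomb-field integral for a single descreening
    sphere).  An isolated atom keeps its intrinsic radius.

    Pairwise descreening double-counts overlap regions, so in densely
    overlapping geometries the summed integrals can exceed the intrinsic
    term; effective radii are clamped at ``r_max`` (a buried-atom
    ceiling, as GB implementations conventionally do).
    """
    coords = np.asarray(coords, dtype=float)
    rho = np.asarray(intrinsic, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("intrinsic radii must be positive")
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any((r < 1e-9) & off):
        raise ValueError("overlapping identical centres")
    rho_i = rho[:, None]
    rho_j = rho[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r + rho_j
        el = np.maximum(np.abs(r - rho_j), rho_i)
        h = 0.5 * (
            1.0 / el
            - 1.0 / u
            + (r / 4.0) * (1.0 / u**2 - 1.0 / el**2)
            + (1.0 / (2.0 * r)) * np.log(el / u)
            + (rho_j**2 / (4.0 * r)) * (1.0 / el**2 - 1.0 / u**2)
        )
    engulfed = r + rho_j <= rho_i
    h = np.where(off & ~engulfed, h, 0.0)
    inv = 1.0 / rho - h.sum(axis=1)
    inv = np.maximum(inv, 1.0 / r_max)
    return 1.0 / inv


def energy_gb(
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    eps_in: float = 1.0,
    eps_out: float = 78.5,
    return_matrix: bool = False,
):
    """Still's generalized Born polar solvation energy.

        E_GB = -(332.0636/2) (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_ij
        f_ij = sqrt(r_ij^2 + R_i R_j exp(-r_ij^2 / (4 R_i R_j)))

    The double sum runs over all ordered pairs including i = j (the Born
    self terms, f_ii = R_i).  With ``return_matrix`` the per-ordered-pair
    contribution matrix is returned (it sums to E_GB).
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("Born radii must be positive")
    tau = (1.0 / eps_in) - (1.0 / eps_out)
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = (diff**2).sum(axis=-1)
    rirj = radii[:, None] * radii[None, :]
    f = np.sqrt(r2 + rirj * np.exp(-r2 / (4.0 * rirj)))
    contrib = -0.5 * COULOMB * tau * (charges[:, None] * charges[None, :]) / f
    if return_matrix:
        return float(contrib.sum()), contrib
    return float(contrib.sum())


def energy_np(
    sasa_value: float,
    slope: float = NP_SLOPE,
    intercept: float = NP_INTERCEPT,
) -> float:
    """Nonpolar solvation: g * SASA + b with the standard constants
    g = 0.00542 kcal/(mol A^2) and b = 0.92 kcal/mol."""
    if sasa_value < 0:
        raise ValueError("SASA must be non-negative")
    return slope * sasa_value + intercept


def frame_energy(
    frame: FiberFrame,
    topology: FiberTopology,
    settings: EnergySettings = EnergySettings(),
) -> EnergyBreakdown:
    """Full MM-GBSA breakdown of one frame."""
    e_gas = energy_gas(frame, topology, settings.cutoff)
    radii = born_radii(frame.coords, topology.born_radius)
    e_gb = energy_gb(
        frame.coords, topology.charges, radii, settings.eps_in, settings.eps_out
    )
    total_sasa, _ = _sasa(
        frame.coords, topology.born_radius, settings.probe, settings.sasa_points
    )
    e_np = energy_np(total_sasa, settings.np_slope, settings.np_intercept)
    return EnergyBreakdown(e_gas=e_gas, e_gb=e_gb, e_np=e_np)


# ---------------------------------------------------------------------------
# assembly energy (two-state bookkeeping)
# ---------------------------------------------------------------------------

@dataclass
class SystemEnergies:
    """Per-frame total energies of one simulated system."""

    totals: np.ndarray           # kcal/mol per frame
    n_monomers: int
    settings: EnergySettings

    def per_monomer(self) -> float:
        return float(np.mean(self.totals)) / self.n_monomers


def ensemble_energies(
    trajectory: Trajectory,
    topology: FiberTopology,
    settings: EnergySettings = EnergySettings(),
    n_monomers: int | None = None,
) -> SystemEnergies:
    totals = np.array(
        [frame_energy(f, topology, settings).total for f in trajectory.frames]
    )
    return SystemEnergies(
        totals=totals,
        n_monomers=n_monomers if n_monomers is not None else topology.n_monomers,
        settings=settings,
    )


def assembly_energy(
    fiber: SystemEnergies, monomer: SystemEnergies
) -> float:
    """Self-assembly energy per monomer:

        dE = <E_fibre> / N  -  <E_monomer>

    i.e. the energy gain for one monomer to sit in the fibre rather than
    be dissolved.  Both ensembles must have been evaluated with identical
    settings.
    """
    if fiber.settings != monomer.settings:
        raise ValueError("ensembles evaluated with different energy settings")
    return fiber.per_monomer() - np.mean(monomer.totals) / monomer.n_monomers


# ---------------------------------------------------------------------------
# per-monomer / pairwise decomposition
# ---------------------------------------------------------------------------

@dataclass
class EnergyDecomposition:
    pairwise: np.ndarray          # (N, N) symmetric, dE_int(n, m); zero diagonal
    pairwise_ele: np.ndarray      # electrostatic (gas Coulomb) component
    pairwise_vdw: np.ndarray      # van der Waals component
    pairwise_sol: np.ndarray      # GB cross-term component (dE_int,sol)
    own: np.ndarray               # (N,) intra-monomer GB + NP share
    n_frames: int = 1

    def __post_init__(self) -> None:
        if not np.allclose(self.pairwise, self.pairwise.T):
            raise ValueError("pairwise matrix must be symmetric")
        if not np.allclose(np.diag(self.pairwise), 0.0):
            raise ValueError("pairwise diagonal must be zero")

    @property
    def n_monomers(self) -> int:
        return self.pairwise.shape[0]

    @property
    def per_monomer(self) -> np.ndarray:
        """dE_n = sum_m dE_int(n, m) + own solvation share."""
        return self.pairwise.sum(axis=1) + self.own

    @property
    def total(self) -> float:
        """Conserved total: half the pairwise sum plus the own terms."""
        return float(0.5 * self.pairwise.sum() + self.own.sum())


def decompose(
    trajectory: Trajectory | FiberFrame,
    topology: FiberTopology,
    settings: EnergySettings = EnergySettings(),
) -> EnergyDecomposition:
    """Time-averaged per-monomer and pairwise energy decomposition.

    dE_int(n, m) collects every gas-phase pair term and every GB cross
    term between atoms of monomers n and m.  Intra-monomer GB terms
    (including self terms) and the per-monomer share of the nonpolar SASA
    term go to the own-terms vector: SASA is a per-atom quantity and is
    never split pairwise.  The bookkeeping conserves the total:
    0.5 * sum_{n != m} dE_int + sum_n own = E_gas + E_GB + E_NP.
    """
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else [trajectory]
    n = topology.n_monomers
    mono = topology.monomer_of_atom
    pair_ele = np.zeros((n, n))
    pair_vdw = np.zeros((n, n))
    pair_sol = np.zeros((n, n))
    own = np.zeros(n)
    for f in frames:
        _, (iu, ju, e_ele, e_vdw) = energy_gas(
            f, topology, settings.cutoff, return_pairs=True
        )
        mi, mj = mono[iu], mono[ju]
        np.add.at(pair_ele, (mi, mj), e_ele)
        np.add.at(pair_ele, (mj, mi), e_ele)
        np.add.at(pair_vdw, (mi, mj), e_vdw)
        np.add.at(pair_vdw, (mj, mi), e_vdw)

        radii = born_radii(f.coords, topology.born_radius)
        _, gb_matrix = energy_gb(
            f.coords,
            topology.charges,
            radii,
            settings.eps_in,
            settings.eps_out,
            return_matrix=True,
        )
        same = mono[:, None] == mono[None, :]
        # ordered-pair matrix: cross terms land twice (n,m)+(m,n), which
        # is exactly the full atom-pair GB interaction between n and m
        cross = np.where(same, 0.0, gb_matrix)
        idx = mono
        comb = idx[:, None] * n + idx[None, :]
        sol_nm = np.bincount(
            comb.ravel(), weights=cross.ravel(), minlength=n * n
        ).reshape(n, n)
        pair_sol += sol_nm + sol_nm.T
        own_gb = np.bincount(idx, weights=np.where(same, gb_matrix, 0.0).sum(axis=1), minlength=n)
        _, per_atom_sasa = _sasa(
            f.coords, topology.born_radius, settings.probe, settings.sasa_points
        )
        own_np = np.bincount(
            idx, weights=settings.np_slope * per_atom_sasa, minlength=n
        ) + settings.np_intercept / n
        own += own_gb + own_np
    n_frames = len(frames)
    pair_ele /= n_frames
    pair_vdw /= n_frames
    pair_sol /= n_frames
    own /= n_frames
    return EnergyDecomposition(
        pairwise=pair_ele + pair_vdw + pair_sol,
        pairwise_ele=pair_ele,
        pairwise_vdw=pair_vdw,
        pairwise_sol=pair_sol,
        own=own,
        n_frames=n_frames,
    )


def neighbor_profile(
    decomposition: EnergyDecomposition,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(k, mean dE_int at separation k, cumulative fraction).

    For k = 1..N//2, the mean of dE_int(n, n +- k) with periodic monomer
    indexing; the cumulative profile shows where the interaction with the
    fibre matrix saturates.
    """
    m = decomposition.pairwise
    n = decomposition.n_monomers
    ks = np.arange(1, n // 2 + 1)
    means = np.empty(len(ks))
    for idx, k in enumerate(ks):
        vals = [m[i, (i + k) % n] for i in range(n)] + [
            m[i, (i - k) % n] for i in range(n)
        ]
        means[idx] = np.mean(vals)
    total = means.sum()
    cumulative = (
        np.cumsum(means) / total if total != 0 else np.zeros_like(means)
    )
    return ks, means, cumulative


# ---------------------------------------------------------------------------
# hydrogen-bond energy bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class HBondEnergy:
    persistent_count: int
    n_monomers: int
    e_hb: float = E_HB_WATER

    def __post_init__(self) -> None:
        if self.persistent_count < 0 or self.n_monomers < 1:
            raise ValueError("counts must be non-negative, monomers >= 1")

    @property
    def hbs_per_bta(self) -> float:
        """Persistent bonds per monomer, doubled because each monomer
        shares a bonding interface with both stacking neighbours."""
        return 2.0 * self.persistent_count / self.n_monomers

    @property
    def delta_e_hbs(self) -> float:
        """H-bond contribution to self-assembly, from the unrounded
        per-monomer count times the per-bond energy in water."""
        return self.hbs_per_bta * self.e_hb


def hbond_energy(
    persistent_count: int, n_monomers: int, e_hb: float = E_HB_WATER
) -> HBondEnergy:
    return HBondEnergy(persistent_count, n_monomers, e_hb)


def energy_ratios(
    delta_e_sol: float,
    hbe: HBondEnergy,
    delta_e_int_sol: float | None = None,
    delta_e_ele: float | None = None,
    rounded_protocol: bool = True,
) -> dict[str, float]:
    """Magnitude ratios dE_sol/dE_HBs and (optionally) dE_int,sol/dE_ele.

    Under the default reporting protocol both operands are first rounded
    to one decimal and the ratio is again reported to one decimal - the
    convention of summary tables where every energy is printed to one
    decimal and ratios are computed from the printed values.
    """
    def _ratio(a: float, b: float) -> float:
        if rounded_protocol:
            a, b = round(a, 1), round(b, 1)
        if b == 0:
            raise ValueError("zero denominator in energy ratio")
        r = abs(a) / abs(b)
        return round(r, 1) if rounded_protocol else r

    out = {"sol_over_hbs": _ratio(delta_e_sol, hbe.delta_e_hbs)}
    if delta_e_int_sol is not None and delta_e_ele is not None:
        out["intsol_over_ele"] = _ratio(delta_e_int_sol, delta_e_ele)
    return out


def energy_histogram_stats(per_monomer: np.ndarray) -> dict[str, float]:
    """Moment statistics of a per-monomer energy profile.

    Skewness is the adjusted Fisher-Pearson (bias-corrected) coefficient;
    a near-Gaussian profile has skewness near zero, while a profile with
    stable domains skews negative.
    """
    x = np.asarray(per_monomer, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "sd": float(np.std(x, ddof=1)),
        "skewness": float(_stats.skew(x, bias=False)),
    }
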