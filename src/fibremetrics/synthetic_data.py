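"""Synthetic fibre trajectories, hydrogen-bond occupancies, energy
profiles, scattering curves and FRET traces.

Every generator emulates the statistical structure that the analysis
modules assume, with known ground truth, so the whole pipeline is
testable without any external data:

* an ideal 48-monomer stack with 3.4 A intercore spacing, a 6.8 nm
  extended diameter and all amide dihedrals at -140 deg (P-helicity);
* relaxed trajectories with Gaussian stacking disorder, a configurable
  P/M/flipped dihedral mixture and axial compression (folding);
* Bernoulli hydrogen-bond presence matrices at prescribed occupancies;
* per-monomer self-assembly energy profiles with optional stable
  domains (runs of consecutive monomers below the fibre mean);
* flexible-cylinder scattering curves over the instrument q-range
  0.15-4.47 1/nm with multiplicative Gaussian noise;
* biexponential mixing (FRET-ratio) traces.

All randomness flows from one integer seed; each generator draws from
its own named substream so that sub-generators are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import (
    AmideGroup,
    FiberFrame,
    FiberTopology,
    Monomer,
    Trajectory,
    place_atom,
)

# benzene-like core geometry (Angstrom)
_RING_RADIUS = 1.39
_C_CARBONYL_RADIUS = 2.89     # carbonyl C, radial extension of the ring
_CO_BOND = 1.23
_CO_ANGLE = 120.0             # CA2-C-O angle
_NH_BOND = 1.0                # N-H
_HB_DONOR_ACCEPTOR = 2.9      # N...O across one stacking interface

# substream ids; a fixed map keeps generators independently reproducible
_STREAMS = {
    "trajectory": 1,
    "hbond": 2,
    "energy": 3,
    "saxs": 4,
    "fret": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class EnergySpec:
    """Ground truth for per-monomer self-assembly energy profiles.

    ``domains`` are runs of consecutive monomers shifted down (more
    favourable) by ``depth``; each run is (start, length, depth) with
    1-based monomer labels, matching the convention of numbering the
    monomers 1..N along the fibre.
    """

    mean: float = -3.0          # kcal/mol, per-monomer baseline
    sd: float = 1.0             # kcal/mol
    domains: list[tuple[int, int, float]] = field(default_factory=list)


@dataclass
class GeneratorConfig:
    n_monomers: int = 48
    intercore_distance: float = 3.4          # Angstrom
    dihedral0: float = -140.0                # degrees, P-helicity start
    extended_diameter: float = 68.0          # Angstrom (6.8 nm)
    n_frames: int = 100
    stacking_sigma: float = 0.0              # Angstrom, jitter of spacing
    lateral_sigma: float = 0.0               # Angstrom, xy jitter of cores
    dihedral_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)  # P, M, flipped
    fold_factor: float = 1.0                 # equilibrated / initial length
    hbond_spec: list[tuple[int, float]] = field(default_factory=list)
    energy_spec: EnergySpec = field(default_factory=EnergySpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError("n_monomers must be >= 2")
        if not self.intercore_distance > 0:
            raise ValueError("intercore_distance must be positive")
        if abs(sum(self.dihedral_mix) - 1.0) > 1e-9:
            raise ValueError("dihedral_mix fractions must sum to 1")
        if any(f < 0 for f in self.dihedral_mix):
            raise ValueError("dihedral_mix fractions must be non-negative")
        if not 0 < self.fold_factor <= 1:
            raise ValueError("fold_factor must lie in (0, 1]")
        if self.stacking_sigma < 0 or self.lateral_sigma < 0:
            raise ValueError("jitter widths must be non-negative")
        for bond_id, occ in self.hbond_spec:
            if not 0 <= occ <= 1:
                raise ValueError(f"occupancy of bond {bond_id} outside [0, 1]")


# ---------------------------------------------------------------------------
# fibre construction
# ---------------------------------------------------------------------------

def build_ideal_fiber(config: GeneratorConfig) -> tuple[FiberTopology, FiberFrame]:
    """Perfectly stacked fibre: cores on the z axis at exactly the
    configured spacing, all 3N amide dihedrals at ``dihedral0``, donors
    aligned N-H...O across each stacking interface, and side beads at the
    extended envelope radius.

    The periodic repeat along z is n_monomers * intercore_distance, so the
    default 48-monomer / 3.4 A build has a 16.32 nm repeat length.
    """
    n = config.n_monomers
    d = config.intercore_distance
    box_z = n * d
    local = _monomer_template(config)
    names_per = local["names"]
    n_per = len(names_per)

    coords = np.zeros((n * n_per, 3))
    names: list[str] = []
    monomers: list[Monomer] = []
    for i in range(n):
        off = i * n_per
        coords[off : off + n_per] = local["coords"] + np.array([0.0, 0.0, i * d])
        names.extend(names_per)
        monomers.append(_index_monomer(i, off, local))

    topo = FiberTopology(
        monomers=monomers,
        atom_names=names,
        charges=np.tile(local["charge"], n),
        lj_epsilon=np.tile(local["eps"], n),
        lj_sigma=np.tile(local["sigma"], n),
        born_radius=np.tile(local["born"], n),
    )
    return topo, FiberFrame(coords=coords, box_z=box_z)


def _monomer_template(config: GeneratorConfig) -> dict:
    """One monomer in its local frame (core centroid at the origin)."""
    names: list[str] = []
    coords: list[np.ndarray] = []
    params: list[tuple[float, float, float, float]] = []  # q, eps, sigma, born
    amide_slots: list[dict[str, int]] = []

    def add(name, xyz, q, eps, sig, born):
        names.append(name)
        coords.append(np.asarray(xyz, float))
        params.append((q, eps, sig, born))
        return len(names) - 1

    add("COR", [0.0, 0.0, 0.0], 0.0, 0.10, 3.5, 1.7)
    d = config.intercore_distance
    for k in range(3):
        theta = np.radians(120.0 * k)
        theta_prev = np.radians(120.0 * k - 60.0)
        ca1 = _RING_RADIUS * np.array([np.cos(theta_prev), np.sin(theta_prev), 0.0])
        ca2 = _RING_RADIUS * np.array([np.cos(theta), np.sin(theta), 0.0])
        cc = _C_CARBONYL_RADIUS * np.array([np.cos(theta), np.sin(theta), 0.0])
        oo = place_atom(ca1, ca2, cc, _CO_BOND, _CO_ANGLE, config.dihedral0)
        # donor geometry: N sits one stacking interface above the acceptor
        # oxygen of the monomer below, H points straight down at it
        nn = oo + np.array([0.0, 0.0, _HB_DONOR_ACCEPTOR - d])
        hh = nn - np.array([0.0, 0.0, _NH_BOND])
        slot = {
            "ca1": add("CA1", ca1, -0.10, 0.086, 3.4, 1.7),
            "ca2": add("CA2", ca2, 0.10, 0.086, 3.4, 1.7),
            "c": add("C", cc, 0.55, 0.086, 3.4, 1.7),
            "o": add("O", oo, -0.55, 0.210, 2.96, 1.5),
            "n": add("N", nn, -0.40, 0.170, 3.25, 1.55),
            "h": add("H", hh, 0.40, 0.015, 1.07, 1.2),
        }
        amide_slots.append(slot)
    r_side = config.extended_diameter / 2.0
    side_slots = []
    for k in range(3):
        theta = np.radians(120.0 * k + 60.0)
        side_slots.append(
            add(
                "SID",
                r_side * np.array([np.cos(theta), np.sin(theta), 0.0]),
                0.0,
                0.10,
                4.0,
                2.0,
            )
        )
    q, eps, sig, born = (np.array(col) for col in zip(*params))
    return {
        "names": names,
        "coords": np.stack(coords),
        "charge": q,
        "eps": eps,
        "sigma": sig,
        "born": born,
        "amide_slots": amide_slots,
        "side_slots": side_slots,
        "core_slot": 0,
    }


def _index_monomer(i: int, offset: int, local: dict) -> Monomer:
    amides = tuple(
        AmideGroup(
            ca1=offset + s["ca1"],
            ca2=offset + s["ca2"],
            c=offset + s["c"],
            o=offset + s["o"],
            n=offset + s["n"],
            h=offset + s["h"],
        )
        for s in local["amide_slots"]
    )
    return Monomer(
        index=i,
        core_ids=(offset + local["core_slot"],),
        amides=amides,
        side_ids=tuple(offset + s for s in local["side_slots"]),
    )


# class -> dihedral sampling window (degrees), comfortably inside the
# P [-180, -90) / M (-90, 0) / flipped (0, 180] classification ranges
_CLASS_WINDOWS = ((-170.0, -100.0), (-80.0, -10.0), (10.0, 170.0))


def perturb_trajectory(
    topology: FiberTopology, config: GeneratorConfig
) -> Trajectory:
    """Relaxed trajectory with stacking disorder, dihedral mixing and
    axial compression.

    Per frame, core spacings are drawn Normal(d, stacking_sigma) truncated
    positive, every amide dihedral is assigned a helicity class from
    ``dihedral_mix`` with an angle uniform inside that class window, and
    all z coordinates are scaled by ``fold_factor`` (axial compression as
    a stand-in for hydrophobic folding).  The periodic repeat is exactly
    fold_factor * n * d.  Identical config and seed give a bit-identical
    trajectory.
    """
    if not 0 < config.fold_factor <= 1:
        raise ValueError("fold_factor must lie in (0, 1]")
    rng = _rng(config.seed, "trajectory")
    n = config.n_monomers
    d = config.intercore_distance
    f = config.fold_factor
    local = _monomer_template(config)
    n_per = len(local["names"])
    box_z = f * n * d

    frames = []
    for _ in range(config.n_frames):
        spacings = rng.normal(d, config.stacking_sigma, size=n)
        while np.any(spacings <= 0):  # truncate at zero, redraw offenders
            bad = spacings <= 0
            spacings[bad] = rng.normal(d, config.stacking_sigma, size=bad.sum())
        z = np.concatenate([[0.0], np.cumsum(spacings[:-1])]) * f
        xy = (
            rng.normal(0.0, config.lateral_sigma, size=(n, 2))
            if config.lateral_sigma > 0
            else np.zeros((n, 2))
        )
        cls = rng.choice(3, size=(n, 3), p=list(config.dihedral_mix))
        lo = np.take(np.array([w[0] for w in _CLASS_WINDOWS]), cls)
        hi = np.take(np.array([w[1] for w in _CLASS_WINDOWS]), cls)
        dihedrals = rng.uniform(lo, hi)

        coords = np.zeros((n * n_per, 3))
        o_positions = np.zeros((n, 3, 3))
        for i in range(n):
            off = i * n_per
            origin = np.array([xy[i, 0], xy[i, 1], z[i]])
            coords[off : off + n_per] = local["coords"] + origin
            for k, slot in enumerate(local["amide_slots"]):
                ca1 = coords[off + slot["ca1"]]
                ca2 = coords[off + slot["ca2"]]
                cc = coords[off + slot["c"]]
                oo = place_atom(ca1, ca2, cc, _CO_BOND, _CO_ANGLE, dihedrals[i, k])
                coords[off + slot["o"]] = oo
                o_positions[i, k] = oo
        # donors track the acceptor below so the hydrogen-bond ladder
        # survives the stacking jitter (interface i-1 -> i, periodic)
        for i in range(n):
            off = i * n_per
            below = o_positions[i - 1].copy()
            if i == 0:
                below[:, 2] -= box_z
            for k, slot in enumerate(local["amide_slots"]):
                nn = below[k] + np.array([0.0, 0.0, _HB_DONOR_ACCEPTOR])
                coords[off + slot["n"]] = nn
                coords[off + slot["h"]] = nn - np.array([0.0, 0.0, _NH_BOND])
        frames.append(FiberFrame(coords=coords, box_z=box_z))
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# hydrogen bonds, energies
# ---------------------------------------------------------------------------

def generate_hbond_occupancy(
    occupancies, n_frames: int, seed: int = 0
) -> np.ndarray:
    """Bernoulli per-frame presence matrix, shape (n_frames, n_bonds)."""
    occupancies = np.asarray(occupancies, dtype=float)
    if np.any((occupancies < 0) | (occupancies > 1)):
        raise ValueError("occupancies must lie in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _rng(seed, "hbond")
    return rng.random((n_frames, occupancies.size)) < occupancies[None, :]


def generate_energy_profile(
    spec: EnergySpec, n_monomers: int, seed: int = 0
) -> np.ndarray:
    """Per-monomer self-assembly energies: Gaussian baseline with the
    configured stable-domain runs shifted down by their depth.

    Domain runs use 1-based (start, length, depth); overlapping runs are
    rejected.
    """
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    covered = np.zeros(n_monomers, dtype=bool)
    for start, length, _depth in spec.domains:
        if start < 1 or start + length - 1 > n_monomers or length < 1:
            raise ValueError(
                f"domain run ({start}, {length}) outside monomers 1..{n_monomers}"
            )
        sl = slice(start - 1, start - 1 + length)
        if covered[sl].any():
            raise ValueError("overlapping domain runs")
        covered[sl] = True
    rng = _rng(seed, "energy")
    values = rng.normal(spec.mean, spec.sd, size=n_monomers)
    for start, length, depth in spec.domains:
        values[start - 1 : start - 1 + length] -= depth
    return values


# ---------------------------------------------------------------------------
# scattering, FRET
# ---------------------------------------------------------------------------

def default_q_grid(n_points: int = 150) -> np.ndarray:
    """Logarithmic grid over the instrument range 0.15-4.47 1/nm."""
    return np.geomspace(0.15, 4.47, n_points)


def generate_saxs_curve(params, q_grid=None, noise_fraction: float = 0.0, seed: int = 0):
    """Scattering profile I(q) = model * (1 + eps), eps ~ N(0, noise_fraction).

    Returns a :class:`fibremetrics.saxs_wlc.SAXSProfile`; the sigma column
    is noise_fraction * model (zero noise gives zero sigma).
    """
    from .saxs_wlc import SAXSProfile, model_intensity

    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.size == 0:
        raise ValueError("empty q grid")
    if np.any(q_grid <= 0) or np.any(np.diff(q_grid) <= 0):
        raise ValueError("q grid must be positive and strictly ascending")
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    model = model_intensity(q_grid, params)
    if noise_fraction > 0:
        eps = _rng(seed, "saxs").normal(0.0, noise_fraction, size=q_grid.size)
    else:
        eps = np.zeros(q_grid.size)
    return SAXSProfile(
        q=q_grid,
        intensity=model * (1.0 + eps),
        sigma=noise_fraction * model,
    )


def generate_fret_trace(fit_params, t_grid, noise_sd: float = 0.0, seed: int = 0):
    """Mixing trace whose FRET ratio follows the biexponential rise

        F(t) = F_plateau - A_fast exp(-t/tau_fast) - A_slow exp(-t/tau_slow)

    plus Gaussian noise of sd ``noise_sd`` on the ratio.  Intensities are
    emitted on a constant total of 1000 counts so the donor and acceptor
    channels carry the ratio exactly.
    """
    from .fret_kinetics import FRETTrace, biexponential

    if fit_params.tau_fast <= 0 or fit_params.tau_slow <= 0:
        raise ValueError("timescales must be positive")
    if fit_params.a_fast < 0 or fit_params.a_slow < 0:
        raise ValueError("amplitudes must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    ratio = biexponential(t_grid, fit_params)
    if noise_sd > 0:
        ratio = ratio + _rng(seed, "fret").normal(0.0, noise_sd, size=t_grid.size)
    total = 1000.0
    i_acceptor = total * ratio
    i_donor = total - i_acceptor
    return FRETTrace(time=t_grid, i_donor=i_donor, i_acceptor=i_acceptor)
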