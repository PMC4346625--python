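"""Structural order analysis of stacked-fibre trajectories.

Covers intercore spacings and their radial distribution function, amide
dihedral helicity classification (P / M / flipped), hydrogen-bond
detection and persistence, fibre dimensions and contraction, solvent
accessible surface area, and detection of stable (below-average energy)
monomer domains.

Conventions
-----------
* The fibre axis is z and periodicity is handled by the minimum-image
  convention along z only; monomer index order defines neighbour order.
* Dihedral angles are reported in (-180, 180].  Helicity classes:
  P for angles in [-180, -90], M in (-90, 0], flipped for positive
  angles; the boundaries -90 and 0 go to P and M respectively.
* "Persistent" hydrogen bonds are those present in strictly more than
  the threshold fraction (default 95%) of the analysed frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .topology import (
    FiberFrame,
    FiberTopology,
    Trajectory,
    dihedral_angles,
    minimum_image_dz,
)


# ---------------------------------------------------------------------------
# intercore spacing and g(r)
# ---------------------------------------------------------------------------

def intercore_distances(frame: FiberFrame, topology: FiberTopology) -> np.ndarray:
    """Consecutive core-centroid distances along the stack, length n.

    The last entry is the wrap-around spacing between the final and first
    monomer through the periodic boundary.
    """
    cent = topology.core_centroids(frame.coords)
    nxt = np.roll(cent, -1, axis=0)
    delta = nxt - cent
    delta[:, 2] = minimum_image_dz(delta[:, 2], frame.box_z)
    return np.linalg.norm(delta, axis=1)


@dataclass
class GofR:
    r: np.ndarray        # bin centres, Angstrom
    g: np.ndarray        # dimensionless
    bin_width: float

    def __post_init__(self) -> None:
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")


def radial_distribution(
    trajectory: Trajectory | FiberFrame,
    topology: FiberTopology | None = None,
    r_max: float = 5.0,
    bin_width: float = 0.1,
    points: np.ndarray | None = None,
    box: tuple[float, float, float] | None = None,
    volume: float | None = None,
) -> GofR:
    """Pair correlation function of core centroids, frame-averaged.

    Distances use the minimum image along z (via each frame's box_z), or
    along all three axes when an explicit orthorhombic ``box`` is given.
    Counts are normalised by the spherical-shell volume and the mean
    point density N/V so that an uncorrelated arrangement averages to 1;
    ``volume`` defaults to the box volume when ``box`` is given and to a
    cylinder of radius r_max and height box_z otherwise.

    ``points`` bypasses the topology: a (n_frames, n_points, 3) array is
    histogrammed directly (used for validation against ideal gases).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if r_max <= bin_width:
        raise ValueError("r_max must exceed bin_width")

    if points is None:
        if topology is None:
            raise ValueError("either a topology or explicit points are required")
        frames = trajectory.frames if isinstance(trajectory, Trajectory) else [trajectory]
        points = np.stack([topology.core_centroids(f.coords) for f in frames])
        box_zs = [f.box_z for f in frames]
    else:
        points = np.asarray(points, dtype=float)
        if points.ndim == 2:
            points = points[None]
        box_zs = [box[2] if box is not None else np.inf] * len(points)

    n_pts = points.shape[1]
    if n_pts < 2:
        raise ValueError("need at least 2 points for a pair correlation")

    # bins centred on multiples of bin_width so a spacing of exactly
    # k * bin_width lands mid-bin
    n_bins = int(np.floor(r_max / bin_width)) + 1
    edges = (np.arange(n_bins + 1) - 0.5) * bin_width
    edges[0] = 0.0
    counts = np.zeros(n_bins)

    for f_idx in range(points.shape[0]):
        p = points[f_idx]
        delta = p[:, None, :] - p[None, :, :]
        if box is not None:
            for ax in range(3):
                delta[:, :, ax] = minimum_image_dz(delta[:, :, ax], box[ax])
        elif np.isfinite(box_zs[f_idx]):
            delta[:, :, 2] = minimum_image_dz(delta[:, :, 2], box_zs[f_idx])
        dist = np.linalg.norm(delta, axis=-1)
        iu = np.triu_indices(n_pts, k=1)
        d = dist[iu]
        counts += 2 * np.histogram(d[d <= edges[-1]], bins=edges)[0]

    if volume is None:
        if box is not None:
            volume = float(np.prod(box))
        else:
            volume = float(np.pi * r_max**2 * np.mean(box_zs))
    density = n_pts / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = points.shape[0] * n_pts * density * shell
    g = counts / norm
    centres = np.arange(n_bins) * bin_width
    return GofR(r=centres, g=g, bin_width=bin_width)


def first_peak(
    g: GofR, search_window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """(r_peak, height) of the maximum of g(r) inside the window.

    Ties break toward smaller r.
    """
    if search_window is None:
        mask = np.ones_like(g.r, dtype=bool)
    else:
        lo, hi = search_window
        mask = (g.r >= lo) & (g.r <= hi)
    if not mask.any():
        raise ValueError("empty search window")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(g.g[idx])]  # argmax returns the first maximum
    return float(g.r[best]), float(g.g[best])


def order_increase(
    g_ref: GofR, g_test: GofR, search_window: tuple[float, float] | None = None
) -> float:
    """Percent change of the first-peak height, test relative to reference."""
    if g_ref.bin_width != g_test.bin_width or len(g_ref.r) != len(g_test.r):
        raise ValueError("curves must share binning")
    _, h_ref = first_peak(g_ref, search_window)
    _, h_test = first_peak(g_test, search_window)
    if h_ref == 0:
        raise ValueError("reference peak height is zero")
    return 100.0 * (h_test - h_ref) / h_ref


# ---------------------------------------------------------------------------
# dihedrals and helicity
# ---------------------------------------------------------------------------

def amide_dihedrals(frame: FiberFrame, topology: FiberTopology) -> np.ndarray:
    """All 3n amide dihedrals (degrees), monomer-major order.

    Collinear quadruplets come back as NaN.
    """
    quads = np.array(
        [am.quadruplet for m in topology.monomers for am in m.amides]
    )
    c = frame.coords
    return dihedral_angles(c[quads[:, 0]], c[quads[:, 1]], c[quads[:, 2]], c[quads[:, 3]])


def classify_helicity(angle: float | np.ndarray) -> np.ndarray:
    """'P', 'M' or 'flipped' per angle; -90 goes to P, 0 to M."""
    angle = np.asarray(angle, dtype=float)
    out = np.where(angle <= -90.0, "P", np.where(angle <= 0.0, "M", "flipped"))
    return out if out.ndim else out[()]


@dataclass
class HelicityStats:
    fraction_p: float        # percent
    fraction_m: float
    fraction_flipped: float
    mean_dihedral: float     # degrees

    def __post_init__(self) -> None:
        total = self.fraction_p + self.fraction_m + self.fraction_flipped
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"helicity fractions sum to {total}, not 100")


def helicity_fractions(
    trajectory: Trajectory | FiberFrame,
    topology: FiberTopology,
    circular_mean: bool = False,
) -> HelicityStats:
    """Time-and-dihedral averaged helicity fractions in percent.

    The mean dihedral is arithmetic by default; a circular mean is
    available since averages of angles that straddle +-180 are otherwise
    ill-defined.
    """
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else [trajectory]
    angles = np.concatenate([amide_dihedrals(f, topology) for f in frames])
    angles = angles[~np.isnan(angles)]
    if angles.size == 0:
        raise ValueError("no valid dihedrals")
    labels = classify_helicity(angles)
    n = angles.size
    if circular_mean:
        rad = np.radians(angles)
        mean = float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))
    else:
        mean = float(angles.mean())
    return HelicityStats(
        fraction_p=100.0 * np.count_nonzero(labels == "P") / n,
        fraction_m=100.0 * np.count_nonzero(labels == "M") / n,
        fraction_flipped=100.0 * np.count_nonzero(labels == "flipped") / n,
        mean_dihedral=mean,
    )


def count_flipped(
    trajectory: Trajectory | FiberFrame, topology: FiberTopology
) -> tuple[float, float]:
    """(count, percent of 3n) of dihedrals with positive angles.

    On a trajectory the count is the per-frame average.
    """
    frames = trajectory.frames if isinstance(trajectory, Trajectory) else [trajectory]
    per_frame = []
    for f in frames:
        ang = amide_dihedrals(f, topology)
        per_frame.append(np.count_nonzero(ang > 0.0))
    count = float(np.mean(per_frame))
    total = 3 * topology.n_monomers
    return count, 100.0 * count / total


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBond:
    donor_monomer: int
    acceptor_monomer: int
    donor_atom: int       # N
    h_atom: int
    acceptor_atom: int    # O


@dataclass
class HBondTable:
    bonds: list[HBond]
    occupancy: np.ndarray      # fraction per bond
    d_cut: float
    angle_cut: float

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if np.any((self.occupancy < 0) | (self.occupancy > 1)):
            raise ValueError("occupancies must lie in [0, 1]")


def _candidate_bonds(topology: FiberTopology) -> list[HBond]:
    """All inter-monomer donor/acceptor pairings between amide slot k of
    one monomer and slot k of any other monomer (the stacking ladder)."""
    out = []
    for mi in topology.monomers:
        for mj in topology.monomers:
            if mi.index == mj.index:
                continue
            for am_i, am_j in zip(mi.amides, mj.amides):
                out.append(
                    HBond(
                        donor_monomer=mi.index,
                        acceptor_monomer=mj.index,
                        donor_atom=am_i.n,
                        h_atom=am_i.h,
                        acceptor_atom=am_j.o,
                    )
                )
    return out


def detect_hbonds(
    frame: FiberFrame,
    topology: FiberTopology,
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
    candidates: list[HBond] | None = None,
) -> list[HBond]:
    """Geometric hydrogen bonds: donor-acceptor heavy-atom distance below
    d_cut and D-H...A angle above angle_cut, minimum image along z."""
    if candidates is None:
        candidates = _candidate_bonds(topology)
    present = []
    c = frame.coords
    for b in candidates:
        n_pos, h_pos, o_pos = c[b.donor_atom], c[b.h_atom], c[b.acceptor_atom]
        if not np.all(np.isfinite(h_pos)):
            raise ValueError(f"missing hydrogen position for donor atom {b.donor_atom}")
        d_no = n_pos - o_pos
        d_no[2] = minimum_image_dz(d_no[2], frame.box_z)
        if np.linalg.norm(d_no) >= d_cut:
            continue
        v1 = n_pos - h_pos
        v2 = o_pos - h_pos
        v2[2] = minimum_image_dz(v2[2], frame.box_z)
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle > angle_cut:
            present.append(b)
    return present


def hbond_occupancy(
    trajectory: Trajectory,
    topology: FiberTopology,
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
    window_fraction: float = 1.0,
) -> HBondTable:
    """Occupancy fraction of every candidate bond over the (trailing
    window of the) trajectory; bonds never present are dropped."""
    traj = trajectory.equilibrated(window_fraction) if window_fraction < 1 else trajectory
    candidates = _candidate_bonds(topology)
    counts = np.zeros(len(candidates))
    index = {b: i for i, b in enumerate(candidates)}
    for f in traj.frames:
        for b in detect_hbonds(f, topology, d_cut, angle_cut, candidates):
            counts[index[b]] += 1
    occ = counts / len(traj.frames)
    keep = occ > 0
    return HBondTable(
        bonds=[b for b, k in zip(candidates, keep) if k],
        occupancy=occ[keep],
        d_cut=d_cut,
        angle_cut=angle_cut,
    )


def persistent_hbonds(
    table: HBondTable, threshold: float = 0.95
) -> tuple[int, list[HBond]]:
    """Bonds with occupancy strictly above the threshold.

    Strict comparison: a bond present exactly 95% of the time does not
    count as persistent.
    """
    mask = table.occupancy > threshold
    return int(mask.sum()), [b for b, m in zip(table.bonds, mask) if m]


# ---------------------------------------------------------------------------
# dimensions, SASA, domains
# ---------------------------------------------------------------------------

def fiber_dimensions(
    frame: FiberFrame, topology: FiberTopology
) -> tuple[float, tuple[float, float]]:
    """(length nm, thickness range nm).

    Length is the periodic repeat (box_z).  Thickness is twice the (5th,
    95th) percentile of side-bead radial distances from the z axis - a
    robust envelope, since a single thickness is ill-defined for a fibre
    whose cross-section varies along its length.
    """
    side_ids = [i for m in topology.monomers for i in m.side_ids]
    radial = np.linalg.norm(frame.coords[side_ids][:, :2], axis=1)
    lo, hi = np.percentile(radial, [5, 95])
    return frame.box_z / 10.0, (2 * lo / 10.0, 2 * hi / 10.0)


def contraction(l0_nm: float, leq_nm: float) -> float:
    """Percent length reduction from the initial to the equilibrated
    fibre; negative values mean the fibre elongated."""
    if l0_nm <= 0:
        raise ValueError("initial length must be positive")
    return 100.0 * (1.0 - leq_nm / l0_nm)


_FIB_CACHE: dict[int, np.ndarray] = {}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit sphere point set."""
    if n not in _FIB_CACHE:
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        _FIB_CACHE[n] = np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
    return _FIB_CACHE[n]


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area, (total, per-atom) A^2.

    Each atom's extended sphere (radius + probe) is sampled with a
    deterministic Fibonacci point set; a point is accessible if it lies
    outside every other extended sphere.  Per-atom values sum to the
    total by construction.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = len(coords)
    ext = radii + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    per_atom = np.zeros(n)
    r_query = ext.max() + ext
    for i in range(n):
        pts = coords[i] + ext[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], r_query[i]) if j != i]
        if neigh:
            nb = np.asarray(neigh)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (ext[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return float(per_atom.sum()), per_atom


def detect_stable_domains(
    energies: np.ndarray, min_run: int = 5, periodic: bool = False
) -> list[tuple[int, int]]:
    """Maximal runs of >= min_run consecutive monomers with energy
    strictly below the fibre mean.

    Returns 1-based (start, end) inclusive, matching the convention of
    numbering monomers 1..N along the fibre.  With ``periodic`` a run may
    wrap the boundary (reported with end < start).
    """
    energies = np.asarray(energies, dtype=float)
    n = energies.size
    if n < min_run:
        raise ValueError("profile shorter than min_run")
    below = energies < energies.mean()
    if below.all():
        return [(1, n)]
    runs = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, n - 1))
    if periodic and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == n - 1:
        first, last = runs[0], runs.pop()
        runs[0] = (last[0], first[1])  # wrapped run, end < start
    out = []
    for s, e in runs:
        length = (e - s + 1) if e >= s else (n - s + e + 1)
        if length >= min_run:
            out.append((s + 1, e + 1))
    return out
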