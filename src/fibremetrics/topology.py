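"""Coarse fibre topology and trajectory containers.

A stacked supramolecular fibre is represented at a deliberately coarse
resolution: one centroid bead per aromatic core, three amide groups per
monomer (each carrying the C_AR-C_AR-C=O-O=C dihedral quadruplet and an
N-H donor), and a ring of side-chain beads that defines the lateral
envelope.  The analyses downstream only consume core positions, amide
dihedrals, hydrogen-bond geometry and per-atom charge/LJ/Born parameters,
so nothing finer is carried.

Lengths are in Angstrom, charges in elementary charge units, energies in
kcal/mol throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AmideGroup:
    """Atom indices of one amide: dihedral quadruplet plus the N-H donor.

    The dihedral is defined over (ca1, ca2, c, o): two aromatic ring
    carbons, the carbonyl carbon and the carbonyl oxygen.  ``o`` doubles
    as the hydrogen-bond acceptor; (``n``, ``h``) is the donor pair.
    """

    ca1: int
    ca2: int
    c: int
    o: int
    n: int
    h: int

    @property
    def quadruplet(self) -> tuple[int, int, int, int]:
        return (self.ca1, self.ca2, self.c, self.o)


@dataclass(frozen=True)
class Monomer:
    index: int
    core_ids: tuple[int, ...]
    amides: tuple[AmideGroup, ...]
    side_ids: tuple[int, ...]

    @property
    def atom_ids(self) -> np.ndarray:
        ids = list(self.core_ids)
        for a in self.amides:
            ids.extend([a.ca1, a.ca2, a.c, a.o, a.n, a.h])
        ids.extend(self.side_ids)
        return np.asarray(sorted(set(ids)), dtype=int)


@dataclass
class FiberTopology:
    """Per-monomer atom bookkeeping plus per-atom parameters.

    The fibre axis is z; the periodic repeat length lives on each frame
    (``FiberFrame.box_z``), not on the topology.
    """

    monomers: list[Monomer]
    atom_names: list[str]
    charges: np.ndarray          # e
    lj_epsilon: np.ndarray       # kcal/mol
    lj_sigma: np.ndarray         # Angstrom
    born_radius: np.ndarray      # Angstrom, intrinsic
    periodic_axis: str = "z"

    def __post_init__(self) -> None:
        if len(self.monomers) < 2:
            raise ValueError("a fibre topology needs at least 2 monomers")
        for m in self.monomers:
            if len(m.amides) != 3:
                raise ValueError(
                    f"monomer {m.index} has {len(m.amides)} amides; expected 3"
                )
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.born_radius = np.asarray(self.born_radius, dtype=float)
        n = self.n_atoms
        for arr, name in (
            (self.charges, "charges"),
            (self.lj_epsilon, "lj_epsilon"),
            (self.lj_sigma, "lj_sigma"),
            (self.born_radius, "born_radius"),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per atom ({n})")

    @property
    def n_monomers(self) -> int:
        return len(self.monomers)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def monomer_of_atom(self) -> np.ndarray:
        """Map atom index -> monomer index."""
        out = np.full(self.n_atoms, -1, dtype=int)
        for m in self.monomers:
            out[m.atom_ids] = m.index
        return out

    def core_centroids(self, coords: np.ndarray) -> np.ndarray:
        """(n_monomers, 3) centroid of the core beads of each monomer."""
        return np.stack(
            [coords[list(m.core_ids)].mean(axis=0) for m in self.monomers]
        )


@dataclass
class FiberFrame:
    coords: np.ndarray   # (n_atoms, 3) Angstrom
    box_z: float         # Angstrom, periodic repeat along z

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.box_z > 0:
            raise ValueError("box_z must be positive")


@dataclass
class Trajectory:
    frames: list[FiberFrame]
    times_ns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.times_ns is None:
            self.times_ns = np.arange(len(self.frames), dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.times_ns.shape != (len(self.frames),):
            raise ValueError("one timestamp per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i) -> FiberFrame:
        return self.frames[i]

    def equilibrated(self, window_fraction: float = 0.25) -> "Trajectory":
        """Trailing slice of the trajectory used for equilibrium averages.

        The default keeps the last quarter of the frames, the convention
        for a production run whose tail is representative of equilibrium.
        """
        if not 0 < window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")
        k = max(1, int(round(window_fraction * len(self.frames))))
        return Trajectory(self.frames[-k:], self.times_ns[-k:])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def minimum_image_dz(dz: np.ndarray, box_z: float) -> np.ndarray:
    """Wrap z-displacements into (-box_z/2, box_z/2]."""
    return dz - box_z * np.round(np.asarray(dz, dtype=float) / box_z)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom d so that |c-d| = bond, angle(b,c,d) = angle_deg and the
    signed dihedral (a,b,c,d) equals dihedral_deg (IUPAC convention).

    Natural-extension-reference-frame construction; the inverse of
    :func:`dihedral_angles`.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("reference atoms a, b, c are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_angles(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> np.ndarray:
    """Signed dihedral angle(s) in degrees, in (-180, 180].

    Vectorised over leading axes.  Collinear triples yield NaN rather than
    an arbitrary angle.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = np.linalg.norm(b1, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1u = b1 / b1n
        v = b0 - np.sum(b0 * b1u, axis=-1, keepdims=True) * b1u
        w = b2 - np.sum(b2 * b1u, axis=-1, keepdims=True) * b1u
        x = np.sum(v * w, axis=-1)
        y = np.sum(np.cross(b1u, v) * w, axis=-1)
        ang = np.degrees(np.arctan2(y, x))
    degenerate = (
        (np.linalg.norm(v, axis=-1) < 1e-9)
        | (np.linalg.norm(w, axis=-1) < 1e-9)
        | (b1n[..., 0] < 1e-12)
    )
    ang = np.where(degenerate, np.nan, ang)
    # map -180 exactly to +180 so the range is (-180, 180]
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return ang
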