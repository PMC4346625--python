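"""File formats: multi-model PDB trajectories, parameter sidecars, 1D
scattering profiles and FRET traces.

Trajectories travel as multi-model PDB (one MODEL per frame) whose CRYST1
record carries the periodic repeat along z.  Per-atom force-field-like
parameters (charge, LJ, intrinsic Born radius) do not fit in PDB columns
and are written to a sidecar CSV keyed by atom id.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .topology import (
    AmideGroup,
    FiberFrame,
    FiberTopology,
    Monomer,
    Trajectory,
)

# generous lateral box so CRYST1 stays well-formed; only the z length is
# meaningful for the (z-periodic) fibre
_LATERAL_BOX = 200.0

_ROLE_BY_NAME = {
    "COR": "core",
    "CA1": "aromatic_c",
    "CA2": "aromatic_c",
    "C": "carbonyl_c",
    "O": "carbonyl_o",
    "N": "amide_n",
    "H": "amide_h",
    "SID": "side_bead",
}


def write_pdb_trajectory(
    path: str | Path, topology: FiberTopology, trajectory: Trajectory
) -> None:
    """Write a multi-model PDB; CRYST1 c-axis = box_z of the first frame."""
    n_frames = len(trajectory)
    n_atoms = topology.n_atoms
    atoms = struc.AtomArray(n_atoms)
    atoms.coord = np.zeros((n_atoms, 3), dtype=np.float32)
    monomer_of = topology.monomer_of_atom
    atoms.chain_id = np.full(n_atoms, "A")
    atoms.res_id = monomer_of + 1
    atoms.res_name = np.full(n_atoms, "BTA")
    atoms.atom_name = np.array(
        [_pdb_atom_name(nm, i) for i, nm in enumerate(topology.atom_names)]
    )
    atoms.element = np.array(
        [_element_of(nm) for nm in topology.atom_names]
    )
    atoms.hetero = np.full(n_atoms, True)

    stack = struc.stack([atoms] * n_frames)
    stack.coord = np.stack(
        [f.coords for f in trajectory.frames]
    ).astype(np.float32)
    box = np.diag(
        [_LATERAL_BOX, _LATERAL_BOX, trajectory.frames[0].box_z]
    )
    stack.box = np.repeat(box[None, :, :], n_frames, axis=0)

    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def read_pdb_trajectory(path: str | Path) -> tuple[Trajectory, np.ndarray]:
    """Read a multi-model PDB; returns the trajectory and residue ids.

    The periodic z length is taken from CRYST1.
    """
    f = pdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    if stack.box is None:
        raise ValueError(f"{path}: missing CRYST1 record (periodic z length)")
    box = np.asarray(stack.box)
    box_z = float(box[2, 2]) if box.ndim == 2 else float(box[0, 2, 2])
    frames = [
        FiberFrame(coords=np.asarray(stack.coord[i], dtype=float), box_z=box_z)
        for i in range(stack.stack_depth())
    ]
    return Trajectory(frames), np.asarray(stack.res_id[:])


def write_parameter_sidecar(path: str | Path, topology: FiberTopology) -> None:
    df = pd.DataFrame(
        {
            "atom_id": np.arange(topology.n_atoms),
            "monomer": topology.monomer_of_atom,
            "atom_name": topology.atom_names,
            "role": [
                _ROLE_BY_NAME.get(nm, "other") for nm in topology.atom_names
            ],
            "charge_e": topology.charges,
            "lj_epsilon_kcal": topology.lj_epsilon,
            "lj_sigma_A": topology.lj_sigma,
            "born_radius_A": topology.born_radius,
        }
    )
    df.to_csv(path, index=False)


def read_parameter_sidecar(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {
        "atom_id",
        "monomer",
        "atom_name",
        "charge_e",
        "lj_epsilon_kcal",
        "lj_sigma_A",
        "born_radius_A",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sidecar missing columns {sorted(missing)}")
    return df.sort_values("atom_id").reset_index(drop=True)


def rebuild_topology(
    sidecar: pd.DataFrame, res_ids: np.ndarray
) -> FiberTopology:
    """Reassemble a FiberTopology from a sidecar table and PDB residue ids.

    Atom roles are taken from the atom_name column written by
    :func:`write_parameter_sidecar`; amide groups are matched up in the
    order they appear within each monomer.
    """
    names = [str(n) for n in sidecar["atom_name"]]
    monomer_ids = np.asarray(sidecar["monomer"], dtype=int)
    monomers = []
    for mi in np.unique(monomer_ids):
        ids = np.flatnonzero(monomer_ids == mi)
        by_name: dict[str, list[int]] = {}
        for i in ids:
            by_name.setdefault(names[i], []).append(int(i))
        amides = tuple(
            AmideGroup(*(by_name[nm][k] for nm in ("CA1", "CA2", "C", "O", "N", "H")))
            for k in range(3)
        )
        monomers.append(
            Monomer(
                index=int(mi),
                core_ids=tuple(by_name.get("COR", [])),
                amides=amides,
                side_ids=tuple(by_name.get("SID", [])),
            )
        )
    return FiberTopology(
        monomers=monomers,
        atom_names=names,
        charges=np.asarray(sidecar["charge_e"], float),
        lj_epsilon=np.asarray(sidecar["lj_epsilon_kcal"], float),
        lj_sigma=np.asarray(sidecar["lj_sigma_A"], float),
        born_radius=np.asarray(sidecar["born_radius_A"], float),
    )


# ---------------------------------------------------------------------------
# 1D profiles
# ---------------------------------------------------------------------------

def write_saxs_profile(path: str | Path, q, intensity, sigma) -> None:
    """Whitespace-delimited 3-column text: q [1/nm], I(q), sigma."""
    data = np.column_stack([q, intensity, sigma])
    header = "q_invnm I sigma"
    np.savetxt(path, data, header=header)


def read_saxs_profile(path: str | Path):
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (q, I, sigma)")
    return data[:, 0], data[:, 1], data[:, 2]


def write_fret_trace(path: str | Path, time_s, i_donor, i_acceptor) -> None:
    pd.DataFrame(
        {"time_s": time_s, "I_donor": i_donor, "I_acceptor": i_acceptor}
    ).to_csv(path, index=False)


def read_fret_trace(path: str | Path):
    df = pd.read_csv(path)
    for col in ("time_s", "I_donor", "I_acceptor"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return (
        df["time_s"].to_numpy(float),
        df["I_donor"].to_numpy(float),
        df["I_acceptor"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _pdb_atom_name(name: str, index: int) -> str:
    # PDB atom names are 4 chars; disambiguate repeated names within a
    # residue by a trailing digit where space allows
    return name[:4]


def _element_of(name: str) -> str:
    if name in ("COR", "SID"):
        return "C"
    if name.startswith("CA") or name == "C":
        return "C"
    return name[0]
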