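"""Trajectory containers, multi-frame XYZ/PDB readers and writers, selections.

Coordinates are stored in Angstrom and times in picoseconds everywhere;
nanometre inputs are converted at the boundary by the callers that accept
them.  Atom roles (ion, phenyl carbon, carboxylate carbon/oxygen, hydroxyl
oxygen, sulfur anchor) are assigned from an explicit sidecar map rather
than from atom-name heuristics, so an unmapped name is a loud error and
never a silent misassignment.

The XYZ dialect carries frame metadata on the comment line::

    time_ps=<t> box=<lx> <ly> <lz>

Multi-frame PDB (MODEL/ENDMDL with a CRYST1 record) is read and written
through MDAnalysis.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

#: Recognized atom role labels.
ROLES = frozenset(
    {"ion", "phenyl_C", "carboxylate_C", "carboxylate_O", "hydroxyl_O", "sulfur", "other"}
)


@dataclass(frozen=True)
class BoxSpec:
    """Periodic slab box: lengths in A, per-axis periodicity flags.

    The default geometry is periodic in x and y and open in z, matching a
    surface slab with bulk solvent above it.
    """

    lx: float
    ly: float
    lz: float
    periodic: tuple[bool, bool, bool] = (True, True, False)

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError(f"box lengths must be positive, got {self.lengths}")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.lx, self.ly, self.lz)

    @property
    def area_xy(self) -> float:
        """In-plane area lx*ly in A^2."""
        return self.lx * self.ly


@dataclass
class Topology:
    """Static per-atom metadata: roles, molecule membership, species names."""

    roles: np.ndarray  # dtype object/str, length n_atoms
    molecule_id: np.ndarray  # int, length n_atoms
    species: np.ndarray  # str, length n_atoms (e.g. LI, NA, K, CS, NH4, TMA)

    def __post_init__(self) -> None:
        self.roles = np.asarray(self.roles, dtype=object)
        self.molecule_id = np.asarray(self.molecule_id, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        n = len(self.roles)
        if len(self.molecule_id) != n or len(self.species) != n:
            raise ValueError("roles, molecule_id and species must have equal length")
        unknown = set(self.roles) - ROLES
        if unknown:
            raise ValueError(f"unknown atom roles: {sorted(unknown)}; allowed: {sorted(ROLES)}")
        self._check_carboxylate_integrity()

    def _check_carboxylate_integrity(self) -> None:
        # every carboxylate_O must live in a molecule with exactly one carboxylate_C
        o_mols = set(self.molecule_id[self.roles == "carboxylate_O"])
        for mol in o_mols:
            in_mol = self.molecule_id == mol
            n_c = int(np.sum(self.roles[in_mol] == "carboxylate_C"))
            if n_c != 1:
                raise ValueError(
                    f"molecule {mol} has carboxylate_O atoms but {n_c} carboxylate_C "
                    "(expected exactly 1)"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.roles)


@dataclass
class Frame:
    """One snapshot: time in ps, positions (n_atoms, 3) in A, and the box."""

    time: float
    positions: np.ndarray
    box: BoxSpec

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (n_atoms, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in frame")


@dataclass
class Trajectory:
    """Time-ordered frames over a fixed topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.positions.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {f.positions.shape[0]} atoms, topology has {n}"
                )
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def box(self) -> BoxSpec:
        if not self.frames:
            raise ValueError("empty trajectory has no box")
        return self.frames[0].box

    def positions_of(self, indices: np.ndarray) -> np.ndarray:
        """Stacked positions (n_frames, len(indices), 3) of selected atoms."""
        return np.stack([f.positions[indices] for f in self.frames])


# ---------------------------------------------------------------------------
# role maps


def load_role_map(path: str | Path) -> dict:
    """Load a YAML sidecar mapping atom names to roles (and molecule ids).

    Schema::

        roles: {NA: ion, CPH: phenyl_C, ...}
        molecule_ids: [0, 0, 1, ...]   # optional, per-atom

    Without ``molecule_ids`` each atom becomes its own molecule.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "roles" not in data:
        raise ValueError(f"role map {path} must be a mapping with a 'roles' key")
    bad = set(data) - {"roles", "molecule_ids"}
    if bad:
        raise ValueError(f"unknown keys in role map {path}: {sorted(bad)}")
    return data


def _topology_from_names(names: Sequence[str], role_map: dict) -> Topology:
    roles_by_name = role_map["roles"]
    unmapped = sorted({n for n in names if n not in roles_by_name})
    if unmapped:
        raise ValueError(f"atom names not covered by the role map: {unmapped}")
    roles = [roles_by_name[n] for n in names]
    mol_ids = role_map.get("molecule_ids")
    if mol_ids is None:
        mol_ids = list(range(len(names)))
    elif len(mol_ids) != len(names):
        raise ValueError(
            f"molecule_ids length {len(mol_ids)} != atom count {len(names)}"
        )
    return Topology(roles=np.array(roles, dtype=object),
                    molecule_id=np.array(mol_ids, dtype=int),
                    species=np.array(list(names), dtype=object))


# ---------------------------------------------------------------------------
# XYZ dialect


def _parse_xyz_comment(comment: str, frame_index: int, dt_fallback: float) -> tuple[float, BoxSpec | None]:
    time = None
    box = None
    for token in comment.split():
        if token.startswith("time_ps="):
            time = float(token.split("=", 1)[1])
        if token.startswith("box="):
            rest = comment.split("box=", 1)[1].split()
            box = BoxSpec(float(rest[0]), float(rest[1]), float(rest[2]))
            break
    if time is None:
        time = frame_index * dt_fallback
    return time, box


def _read_xyz(path: Path, role_map: dict, dt_fallback: float) -> Trajectory:
    frames: list[Frame] = []
    names: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    fidx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"malformed XYZ frame header at line {i + 1} of {path}") from exc
        if i + 1 + n >= len(lines) + 1 and len(lines) < i + 2 + n:
            raise ValueError(f"truncated XYZ frame {fidx} in {path}")
        time, box = _parse_xyz_comment(lines[i + 1], fidx, dt_fallback)
        if box is None:
            raise ValueError(f"XYZ frame {fidx} comment line lacks a box= record")
        frame_names: list[str] = []
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise ValueError(f"malformed atom line in XYZ frame {fidx} of {path}")
            frame_names.append(parts[0])
            pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if names is None:
            names = frame_names
        elif len(frame_names) != len(names):
            raise ValueError(
                f"atom-count mismatch at frame {fidx}: {len(frame_names)} vs {len(names)}"
            )
        frames.append(Frame(time=time, positions=pos, box=box))
        i += 2 + n
        fidx += 1
    if names is None:
        raise ValueError(f"no frames found in {path}")
    topo = _topology_from_names(names, role_map)
    return Trajectory(topology=topo, frames=frames)


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for f in traj.frames:
            b = f.box
            fh.write(f"{traj.topology.n_atoms}\n")
            fh.write(f"time_ps={f.time:.6f} box={b.lx:.6f} {b.ly:.6f} {b.lz:.6f}\n")
            for name, (x, y, z) in zip(traj.topology.species, f.positions):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# PDB through MDAnalysis


def _read_pdb(path: Path, role_map: dict, dt_fallback: float) -> Trajectory:
    import MDAnalysis as mda

    # global CRYST1 (written once, before the first MODEL) — the per-frame
    # reader only sees records inside each MODEL block
    global_box = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                global_box = BoxSpec(
                    float(line[6:15]), float(line[15:24]), float(line[24:33])
                )
                break

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        names = [a.name for a in u.atoms]
        topo = _topology_from_names(names, role_map)
        # resids from the PDB override the sidecar's default 1-atom molecules
        if "molecule_ids" not in role_map:
            topo = Topology(
                roles=topo.roles,
                molecule_id=np.array([a.resid for a in u.atoms], dtype=int),
                species=topo.species,
            )
        frames = []
        for fidx, ts in enumerate(u.trajectory):
            dims = ts.dimensions
            if dims is not None and dims[0] > 0:
                box = BoxSpec(float(dims[0]), float(dims[1]), float(dims[2]))
            elif global_box is not None:
                box = global_box
            else:
                raise ValueError(f"PDB frame {fidx} lacks a CRYST1 box record")
            frames.append(
                Frame(time=fidx * dt_fallback, positions=ts.positions.astype(float).copy(), box=box)
            )
    return Trajectory(topology=topo, frames=frames)


def _write_pdb(traj: Trajectory, path: Path) -> None:
    import MDAnalysis as mda

    topo = traj.topology
    mols, resindex = np.unique(topo.molecule_id, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=topo.n_atoms,
        n_residues=len(mols),
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(s) for s in topo.species])
    u.add_TopologyAttr("resnames", ["MOL"] * len(mols))
    u.add_TopologyAttr("resids", mols)
    b = traj.box
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=topo.n_atoms) as w:
            for f in traj.frames:
                u.atoms.positions = f.positions
                u.dimensions = [b.lx, b.ly, b.lz, 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# public I/O API


def read_trajectory(
    path: str | Path,
    fmt: str | None = None,
    role_map_path: str | Path | None = None,
    role_map: dict | None = None,
    dt_fallback: float = 1.0,
) -> Trajectory:
    """Read a multi-frame XYZ or PDB trajectory with a role-map sidecar.

    Parameters
    ----------
    path
        Trajectory file.
    fmt
        "xyz" or "pdb"; inferred from the suffix when omitted.
    role_map_path, role_map
        Sidecar mapping atom names to roles (exactly one must be given).
    dt_fallback
        Frame spacing (ps) used when the file stores no times (PDB, or XYZ
        without time_ps records).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if (role_map is None) == (role_map_path is None):
        raise ValueError("provide exactly one of role_map / role_map_path")
    if role_map is None:
        role_map = load_role_map(role_map_path)
    if fmt == "xyz":
        return _read_xyz(path, role_map, dt_fallback)
    if fmt == "pdb":
        return _read_pdb(path, role_map, dt_fallback)
    raise ValueError(f"unsupported trajectory format: {fmt!r} (use 'xyz' or 'pdb')")


def write_trajectory(traj: Trajectory, path: str | Path, fmt: str | None = None) -> None:
    """Write a trajectory as multi-frame XYZ (metadata comment line) or PDB."""
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        _write_xyz(traj, path)
    elif fmt == "pdb":
        _write_pdb(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format: {fmt!r} (use 'xyz' or 'pdb')")


def default_role_map(topology: Topology) -> dict:
    """Sidecar dict reproducing an in-memory topology (for write/read cycles)."""
    return {
        "roles": {str(s): str(r) for s, r in zip(topology.species, topology.roles)},
        "molecule_ids": [int(m) for m in topology.molecule_id],
    }


# ---------------------------------------------------------------------------
# selections and windows


def select(
    topology: Topology,
    role: str | Iterable[str] | None = None,
    species: str | Iterable[str] | None = None,
    molecule: int | Iterable[int] | None = None,
) -> np.ndarray:
    """Sorted unique atom indices matching all given predicates.

    Predicates combine by intersection; each accepts a single value or an
    iterable of values (union within the predicate).
    """
    mask = np.ones(topology.n_atoms, dtype=bool)

    def _as_set(v):
        if isinstance(v, (str, int, np.integer)):
            return {v}
        return set(v)

    if role is not None:
        wanted = _as_set(role)
        unknown = wanted - ROLES
        if unknown:
            raise ValueError(f"unknown role label(s): {sorted(unknown)}")
        mask &= np.isin(topology.roles, list(wanted))
    if species is not None:
        mask &= np.isin(topology.species, list(_as_set(species)))
    if molecule is not None:
        mask &= np.isin(topology.molecule_id, list(_as_set(molecule)))
    return np.flatnonzero(mask)


def analysis_window(
    traj: Trajectory,
    last_fraction: float | None = None,
    time_range: tuple[float, float] | None = None,
) -> Trajectory:
    """Restrict a trajectory to an analysis window; the original is untouched.

    Either the trailing fraction of frames (e.g. 0.4 for the last 40% of
    sampling) or an inclusive [t0, t1] time range in ps.
    """
    if (last_fraction is None) == (time_range is None):
        raise ValueError("provide exactly one of last_fraction / time_range")
    if last_fraction is not None:
        if not 0 < last_fraction <= 1:
            raise ValueError(f"last_fraction must be in (0, 1], got {last_fraction}")
        n_keep = int(round(last_fraction * traj.n_frames))
        frames = traj.frames[traj.n_frames - n_keep :]
    else:
        t0, t1 = time_range
        times = traj.times
        if len(times) and (t0 > times[-1] or t1 < times[0]):
            raise ValueError(
                f"window [{t0}, {t1}] ps lies outside the trajectory span "
                f"[{times[0]}, {times[-1]}] ps"
            )
        frames = [f for f in traj.frames if t0 <= f.time <= t1]
    if not frames:
        raise ValueError("analysis window selects no frames")
    return Trajectory(topology=traj.topology, frames=list(frames))
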