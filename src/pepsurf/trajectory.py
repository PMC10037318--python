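"""Trajectory containers and I/O.

The in-memory model is deliberately small: a :class:`Trajectory` holds one
shared topology (a list of :class:`Atom`) plus an ordered list of
:class:`Frame` coordinate snapshots.  All coordinates are stored in Angstrom;
nanometre-based inputs are converted on read.  Gold slab atoms are flagged by
element so downstream stages can split the system into the Au(111) slab and
the adsorbed peptide without re-deriving chemistry.

Standard structure/trajectory formats (PDB, GRO, XTC, DCD, TRR...) are read
through MDAnalysis.  A plain-text frame format (written and read here) is used
by the synthetic-data generator and for lossless round-trips in tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError, StructureError

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "ResidueGroup",
    "load_trajectory",
    "read_text_trajectory",
    "write_text_trajectory",
    "partition_atoms",
    "write_atom_table",
]

NM_TO_ANGSTROM = 10.0

#: Atom-name prefixes recognised as gold when no element is given.
_GOLD_NAMES = {"AU", "AUI", "AUS", "AUB"}


def _infer_element(name: str, resname: str) -> str:
    """Best-effort element from an atom name (PDB-style heuristics)."""
    stripped = name.strip().upper()
    if stripped in _GOLD_NAMES or resname.strip().upper() in {"AU", "AUS", "SLAB"}:
        return "Au"
    # leading digits (e.g. "1HB") then first alphabetic character
    for ch in stripped:
        if ch.isalpha():
            return ch.capitalize()
    return "X"


@dataclass(frozen=True)
class Atom:
    """One topology entry; ``is_slab`` marks gold atoms."""

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    is_slab: bool = False

    def __post_init__(self):
        if self.index < 0:
            raise StructureError(f"atom index must be >= 0, got {self.index}")
        if self.residue_index < 1 and not self.is_slab:
            raise StructureError(
                f"residue index must be >= 1, got {self.residue_index}"
            )


@dataclass
class Frame:
    """Coordinates (n_atoms, 3) in Angstrom, box lengths in Angstrom, time in ps."""

    coordinates: np.ndarray
    box: tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError(
                f"coordinates must have shape (n, 3), got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("non-finite coordinates in frame")
        if any(b <= 0 for b in self.box):
            raise StructureError(f"box lengths must be positive, got {self.box}")


@dataclass
class Trajectory:
    """Shared topology + ordered frames; every frame has the same atom count."""

    atoms: list[Atom]
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        if not self.frames:
            raise StructureError("a trajectory needs at least one frame")
        n = len(self.atoms)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise StructureError(
                    f"frame {i} has {fr.coordinates.shape[0]} atoms, topology has {n}"
                )
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise StructureError("duplicate atom indices in topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinate_array(self) -> np.ndarray:
        """All coordinates as one (n_frames, n_atoms, 3) array (Angstrom)."""
        return np.stack([fr.coordinates for fr in self.frames])


@dataclass(frozen=True)
class ResidueGroup:
    """Atoms of one peptide residue, ordered by atom index."""

    residue_index: int
    residue_name: str
    atom_indices: tuple[int, ...]

    @property
    def label(self) -> str:
        return f"{self.residue_name}{self.residue_index}"


# ---------------------------------------------------------------------------
# plain-text internal format
#
#   # pepsurf-traj 1
#   natoms 5
#   frame time 0.0 box 58.0 61.0 68.0
#   0 AU AUS 0 0.000 0.000 0.000
#   ...
#
# Rows: index name resname resid x y z.  Units as written (Angstrom by the
# writer); the reader converts nm inputs when asked to.
# ---------------------------------------------------------------------------

_MAGIC = "# pepsurf-traj 1"


def write_text_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write the internal plain-text format (Angstrom)."""
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"natoms {traj.n_atoms}\n")
        for fr in traj.frames:
            bx, by, bz = fr.box
            fh.write(f"frame time {fr.time:.6f} box {bx:.6f} {by:.6f} {bz:.6f}\n")
            for atom, xyz in zip(traj.atoms, fr.coordinates):
                fh.write(
                    f"{atom.index} {atom.name} {atom.residue_name} "
                    f"{atom.residue_index} "
                    f"{xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n"
                )


def read_text_trajectory(
    path: str | os.PathLike, length_unit: str = "angstrom"
) -> Trajectory:
    """Read the internal plain-text format.

    ``length_unit`` names the unit the file was written in; coordinates are
    converted to Angstrom internally.
    """
    scale = _unit_scale(length_unit)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise StructureError(f"{path}: not a pepsurf text trajectory")
        line = fh.readline().split()
        if len(line) != 2 or line[0] != "natoms":
            raise StructureError(f"{path}: missing natoms header")
        natoms = int(line[1])

        atoms: list[Atom] | None = None
        frames: list[Frame] = []
        while True:
            header = fh.readline()
            if not header:
                break
            parts = header.split()
            if parts[0] != "frame":
                raise StructureError(f"{path}: expected frame header, got {header!r}")
            time = float(parts[2])  # ps regardless of length unit
            box = tuple(float(v) * scale for v in parts[4:7])
            coords = np.empty((natoms, 3))
            frame_atoms: list[Atom] = []
            for i in range(natoms):
                row = fh.readline().split()
                if len(row) != 7:
                    raise StructureError(
                        f"{path}: frame {len(frames)} has fewer than "
                        f"{natoms} atom rows"
                    )
                name, resname, resid = row[1], row[2], int(row[3])
                element = _infer_element(name, resname)
                # atom index is the coordinate row position; the file's index
                # column is informational only
                frame_atoms.append(
                    Atom(
                        index=i,
                        name=name,
                        element=element,
                        residue_index=resid,
                        residue_name=resname,
                        is_slab=element == "Au",
                    )
                )
                coords[i] = [float(row[4]), float(row[5]), float(row[6])]
            if atoms is None:
                atoms = frame_atoms
            frames.append(Frame(coordinates=coords * scale, box=box, time=time))
    if atoms is None:
        raise StructureError(f"{path}: no frames found")
    return Trajectory(atoms=atoms, frames=frames)


def _unit_scale(length_unit: str) -> float:
    if length_unit == "angstrom":
        return 1.0
    if length_unit == "nanometer":
        return NM_TO_ANGSTROM
    raise ConfigurationError(
        f"unknown length unit {length_unit!r}; use 'angstrom' or 'nanometer'"
    )


# ---------------------------------------------------------------------------
# MDAnalysis adapter + unified loader
# ---------------------------------------------------------------------------

_TEXT_EXTS = {".ptraj", ".pstxt"}


def _is_text_format(path: str | os.PathLike) -> bool:
    if os.path.splitext(str(path))[1].lower() in _TEXT_EXTS:
        return True
    try:
        with open(path) as fh:
            return fh.readline().rstrip("\n") == _MAGIC
    except (OSError, UnicodeDecodeError):
        return False


def _from_mdanalysis(topology: str, frame_paths: list[str]) -> Trajectory:
    import MDAnalysis as mda

    uni = mda.Universe(topology, *frame_paths) if frame_paths else mda.Universe(topology)
    atoms: list[Atom] = []
    for i, at in enumerate(uni.atoms):
        try:
            element = at.element.capitalize() if at.element else ""
        except mda.exceptions.NoDataError:
            element = ""
        if not element:
            element = _infer_element(at.name, at.resname)
        atoms.append(
            Atom(
                index=i,
                name=at.name,
                element=element,
                residue_index=int(at.resid),
                residue_name=at.resname,
                is_slab=element == "Au",
            )
        )
    frames: list[Frame] = []
    for ts in uni.trajectory:
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            box = (1e4, 1e4, 1e4)  # open boundaries: effectively non-periodic
        else:
            box = tuple(float(v) for v in ts.dimensions[:3])
        frames.append(
            Frame(
                coordinates=ts.positions.astype(float).copy(),
                box=box,
                time=float(getattr(ts, "time", 0.0) or 0.0),
            )
        )
    return Trajectory(atoms=atoms, frames=frames)


def load_trajectory(
    topology_path: str | os.PathLike,
    frame_paths: list[str | os.PathLike] | None = None,
    length_unit: str = "angstrom",
) -> Trajectory:
    """Load a trajectory from standard formats or the internal text format.

    Parameters
    ----------
    topology_path:
        PDB/GRO file (atom names, residues) or an internal-format file that
        carries its own topology.
    frame_paths:
        Additional coordinate files (XTC/DCD/GRO/PDB or internal format)
        appended in order.  May be empty when ``topology_path`` has frames.
    length_unit:
        Unit of internal-format files ('angstrom' or 'nanometer').  Formats
        read through MDAnalysis are normalised to Angstrom automatically.

    All coordinates come back in Angstrom.  Every frame file must match the
    topology's atom count.
    """
    _unit_scale(length_unit)  # validate early
    frame_paths = [str(p) for p in (frame_paths or [])]
    topology_path = str(topology_path)
    for path in [topology_path, *frame_paths]:
        if not os.path.exists(path):
            raise StructureError(f"no such file: {path}")

    if _is_text_format(topology_path):
        traj = read_text_trajectory(topology_path, length_unit)
        for fp in frame_paths:
            extra = read_text_trajectory(fp, length_unit)
            if extra.n_atoms != traj.n_atoms:
                raise StructureError(
                    f"{fp}: atom count {extra.n_atoms} does not match "
                    f"topology ({traj.n_atoms})"
                )
            traj.frames.extend(extra.frames)
        return traj

    mda_frames = [fp for fp in frame_paths if not _is_text_format(fp)]
    text_frames = [fp for fp in frame_paths if _is_text_format(fp)]
    try:
        traj = _from_mdanalysis(topology_path, mda_frames)
    except (ValueError, OSError) as exc:
        raise StructureError(f"failed to load {topology_path}: {exc}") from exc
    for fp in text_frames:
        extra = read_text_trajectory(fp, length_unit)
        if extra.n_atoms != traj.n_atoms:
            raise StructureError(
                f"{fp}: atom count {extra.n_atoms} does not match "
                f"topology ({traj.n_atoms})"
            )
        traj.frames.extend(extra.frames)
    return traj


# ---------------------------------------------------------------------------
# slab / peptide partition
# ---------------------------------------------------------------------------


def partition_atoms(
    traj: Trajectory, slab_indices: set[int] | None = None
) -> tuple[frozenset[int], list[ResidueGroup]]:
    """Split the topology into gold-slab atom indices and peptide residues.

    Slab membership defaults to ``element == "Au"``; an explicit atom-index
    set overrides that for exotic topologies.  Non-slab atoms are grouped by
    residue index and returned ordered by residue index.  Atoms that are
    neither gold nor peptide are assumed stripped upstream; anything non-gold
    is treated as peptide here.
    """
    if slab_indices is not None:
        slab = frozenset(int(i) for i in slab_indices)
    else:
        slab = frozenset(a.index for a in traj.atoms if a.is_slab)
    if not slab:
        raise InputError("no slab present: no Au atoms found and no override given")

    residues: dict[int, list[Atom]] = {}
    for atom in traj.atoms:
        if atom.index in slab:
            continue
        residues.setdefault(atom.residue_index, []).append(atom)
    if not residues:
        raise InputError("no peptide present: every atom belongs to the slab")

    groups = [
        ResidueGroup(
            residue_index=resid,
            residue_name=members[0].residue_name,
            atom_indices=tuple(sorted(a.index for a in members)),
        )
        for resid, members in sorted(residues.items())
    ]
    return slab, groups


def write_atom_table(traj: Trajectory, path: str | os.PathLike) -> None:
    """TSV dump of the topology (one row per atom)."""
    with open(path, "w") as fh:
        fh.write("index\tname\telement\tresidue_index\tresidue_name\tis_slab\n")
        for a in traj.atoms:
            fh.write(
                f"{a.index}\t{a.name}\t{a.element}\t{a.residue_index}\t"
                f"{a.residue_name}\t{int(a.is_slab)}\n"
            )
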