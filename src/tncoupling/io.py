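"""Topology/trajectory I/O and region selection.

Reads a PDB topology (ATOM/HETATM records) into a lightweight
:class:`Topology`, reads coordinate frames from multi-model PDB, DCD or
XTC files into a :class:`Trajectory`, and resolves named
:class:`RegionSpec` selections (chain + residue ranges + optional atom
name filter) to stable atom index arrays.

Coordinates are always in Angstrom.  PDB parsing and writing is done
in-package so that parse errors carry line numbers and round trips are
exact to the format's 3-decimal precision; the binary DCD/XTC formats go
through MDAnalysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "RegionSpec",
    "StructureError",
    "load_topology",
    "load_trajectory",
    "resolve",
    "write_pdb",
    "write_trajectory",
]

#: frames per ns used when no configuration supplies one (0.4 ns/frame,
#: i.e. a 1500 ns run stored as 3750 frames)
DEFAULT_FRAME_INTERVAL_NS = 0.4


class StructureError(ValueError):
    """Raised for malformed structure files or invalid selections."""


@dataclass(frozen=True)
class Atom:
    index: int            # 0-based, contiguous over the topology
    name: str             # PDB atom name, stripped
    element: str          # element symbol, best effort from columns 77-78
    residue_number: int   # author numbering, 1-based per chain
    residue_name: str
    chain_id: str
    is_hetero: bool = False


@dataclass
class Topology:
    """Atom table of a structure; substrate for all selections."""

    atoms: list[Atom]
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for i, a in enumerate(self.atoms):
            if a.index != i:
                raise StructureError(
                    f"atom indices must be contiguous from 0; atom {i} has index {a.index}"
                )
            key = (a.chain_id, a.residue_number, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom {key!r} in topology")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain_id, residue_number, residue_name) in file order."""
        out: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.residue_name)
            if not out or out[-1] != key:
                out.append(key)
        return out

    def hetero_residues(self) -> list[tuple[str, int, str]]:
        het = set()
        for a in self.atoms:
            if a.is_hetero:
                het.add((a.chain_id, a.residue_number, a.residue_name))
        return sorted(het)


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates bound to a Topology."""

    coordinates: np.ndarray           # (n_frames, n_atoms, 3), Angstrom
    frame_interval_ns: float = DEFAULT_FRAME_INTERVAL_NS
    run_id: str = "run"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructureError(
                f"coordinates must be (frames, atoms, 3); got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise StructureError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise StructureError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class RegionSpec:
    """A named selection: chain + residue range(s) + optional atom names.

    ``members`` is a sequence of (chain_id, (first_resid, last_resid),
    atom_names) entries; ``atom_names=None`` keeps every atom of the
    residue.  ``ca_only=True`` additionally restricts to CA atoms.
    """

    label: str
    members: tuple = ()
    ca_only: bool = False

    @staticmethod
    def chain_range(
        label: str,
        chain_id: str,
        first: int,
        last: int,
        atom_names: Optional[Sequence[str]] = None,
        ca_only: bool = False,
    ) -> "RegionSpec":
        names = tuple(atom_names) if atom_names is not None else None
        return RegionSpec(label, ((chain_id, (first, last), names),), ca_only)


def _parse_atom_record(line: str, lineno: int, index: int) -> Atom:
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resid_s = line[22:26].strip()
        icode = line[26].strip()
        resid = int(resid_s)
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise StructureError(f"malformed ATOM/HETATM record at line {lineno}: {line.rstrip()!r}") from exc
    if icode:
        raise StructureError(
            f"insertion code {icode!r} at line {lineno} is not supported; "
            "renumber residues before loading"
        )
    if not name or not resname:
        raise StructureError(f"malformed ATOM/HETATM record at line {lineno}: missing atom or residue name")
    if not element:
        # fall back on the first alphabetic character of the atom name
        element = next((c for c in name if c.isalpha()), "X")
    return Atom(
        index=index,
        name=name,
        element=element,
        residue_number=resid,
        residue_name=resname,
        chain_id=chain,
        is_hetero=line.startswith("HETATM"),
    )


def _parse_coords(line: str, lineno: int) -> tuple[float, float, float]:
    try:
        return (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except (ValueError, IndexError) as exc:
        raise StructureError(f"malformed coordinates at line {lineno}: {line.rstrip()!r}") from exc


def load_topology(path: str | os.PathLike) -> Topology:
    """Parse the ATOM/HETATM records of a PDB file (first MODEL only).

    Ligand (HETATM) atoms are retained and flagged ``is_hetero``.
    """
    atoms: list[Atom] = []
    in_model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                in_model += 1
                if in_model > 1:
                    break
            elif rec.startswith("ENDMDL"):
                break
            elif rec.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_atom_record(line, lineno, len(atoms)))
    if not atoms:
        raise StructureError(f"no ATOM/HETATM records found in {path}")
    return Topology(atoms, source_path=str(path))


def _load_multimodel_pdb(path: str | os.PathLike, n_atoms: int) -> np.ndarray:
    frames: list[np.ndarray] = []
    current: list[tuple[float, float, float]] = []
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                current = []
            elif rec.startswith("ENDMDL"):
                if len(current) != n_atoms:
                    raise StructureError(
                        f"frame {len(frames)} of {path} has {len(current)} atoms, "
                        f"topology has {n_atoms}"
                    )
                frames.append(np.array(current, dtype=float))
                current = []
            elif rec.startswith(("ATOM", "HETATM")):
                current.append(_parse_coords(line, lineno))
    if not saw_model:
        # single-model PDB without MODEL/ENDMDL wrapping
        if len(current) != n_atoms:
            raise StructureError(
                f"{path}: found {len(current)} atoms, topology has {n_atoms}"
            )
        frames.append(np.array(current, dtype=float))
    elif current:
        raise StructureError(f"truncated file {path}: frame {len(frames)} lacks ENDMDL")
    if not frames:
        raise StructureError(f"no frames found in {path}")
    return np.stack(frames)


def _load_binary_trajectory(path: str, n_atoms: int) -> np.ndarray:
    # lazy import: MDAnalysis start-up is slow and only binary formats need it
    import MDAnalysis as mda

    ext = os.path.splitext(path)[1].lower()
    reader_cls = {
        ".dcd": mda.coordinates.DCD.DCDReader,
        ".xtc": mda.coordinates.XTC.XTCReader,
    }[ext]
    try:
        reader = reader_cls(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise StructureError(f"cannot read trajectory {path}: {exc}") from exc
    with reader:
        if reader.n_atoms != n_atoms:
            raise StructureError(
                f"{path} has {reader.n_atoms} atoms per frame, topology has {n_atoms}"
            )
        frames = [ts.positions.astype(float).copy() for ts in reader]
    if not frames:
        raise StructureError(f"no frames found in {path}")
    return np.stack(frames)


def load_trajectory(
    path: str | os.PathLike,
    topology: Topology,
    frame_interval_ns: float = DEFAULT_FRAME_INTERVAL_NS,
    run_id: Optional[str] = None,
) -> Trajectory:
    """Load frames from a multi-model PDB, DCD or XTC file.

    The atom count of every frame must match ``topology``; the frame
    interval is configuration, not read from the file (the default,
    0.4 ns/frame, corresponds to a 1500 ns run stored as 3750 frames).
    """
    path = str(path)
    if os.path.getsize(path) == 0:
        raise StructureError(f"empty trajectory file: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".dcd", ".xtc"):
        coords = _load_binary_trajectory(path, topology.n_atoms)
    else:
        coords = _load_multimodel_pdb(path, topology.n_atoms)
    rid = run_id if run_id is not None else os.path.splitext(os.path.basename(path))[0]
    return Trajectory(coords, frame_interval_ns=frame_interval_ns, run_id=rid)


def resolve(spec: RegionSpec, topology: Topology) -> np.ndarray:
    """Resolve a RegionSpec to a sorted array of atom indices.

    Indices are ordered by (chain, residue number, atom index), so a
    helix selection runs N- to C-terminal; overlapping member ranges
    contribute each atom once.
    """
    chains = set(topology.chains)
    picked: dict[int, tuple[str, int, int]] = {}
    for chain_id, (first, last), atom_names in spec.members:
        if chain_id not in chains:
            raise StructureError(
                f"selection {spec.label!r}: chain {chain_id!r} not in topology "
                f"(chains: {sorted(chains)})"
            )
        wanted = None if atom_names is None else {n.upper() for n in atom_names}
        for a in topology.atoms:
            if a.chain_id != chain_id or not (first <= a.residue_number <= last):
                continue
            if wanted is not None and a.name.upper() not in wanted:
                continue
            if spec.ca_only and a.name.upper() != "CA":
                continue
            picked[a.index] = (a.chain_id, a.residue_number, a.index)
    if not picked:
        raise StructureError(f"selection {spec.label!r} resolves to no atoms")
    order = sorted(picked, key=picked.__getitem__)
    return np.array(order, dtype=int)


# ---------------------------------------------------------------------------
# writing

def _format_atom_line(a: Atom, xyz: Sequence[float], serial: int) -> str:
    rec = "HETATM" if a.is_hetero else "ATOM  "
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (
        f"{rec}{serial:5d} {name:<4.4s} {a.residue_name:<3.3s} {a.chain_id:1.1s}"
        f"{a.residue_number:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}\n"
    )


def write_pdb(path: str | os.PathLike, topology: Topology, coordinates: np.ndarray) -> None:
    """Write a single-frame PDB for ``topology`` with the given coordinates."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (topology.n_atoms, 3):
        raise StructureError(
            f"coordinates shape {coordinates.shape} does not match topology ({topology.n_atoms} atoms)"
        )
    with open(path, "w") as fh:
        for a in topology.atoms:
            fh.write(_format_atom_line(a, coordinates[a.index], serial=a.index + 1))
        fh.write("END\n")


def write_trajectory(
    path: str | os.PathLike,
    topology: Topology,
    trajectory: Trajectory,
) -> None:
    """Write a trajectory as multi-model PDB (.pdb) or DCD (.dcd)."""
    if trajectory.n_atoms != topology.n_atoms:
        raise StructureError(
            f"trajectory has {trajectory.n_atoms} atoms, topology has {topology.n_atoms}"
        )
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".dcd":
        import MDAnalysis as mda

        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        with mda.coordinates.DCD.DCDWriter(str(path), n_atoms=topology.n_atoms) as w:
            for frame in trajectory.coordinates:
                u.atoms.positions = frame.astype(np.float32)
                w.write(u.atoms)
        return
    with open(path, "w") as fh:
        for i, frame in enumerate(trajectory.coordinates, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            for a in topology.atoms:
                fh.write(_format_atom_line(a, frame[a.index], serial=a.index + 1))
            fh.write("ENDMDL\n")
        fh.write("END\n")
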