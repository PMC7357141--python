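"""Atomic structures, multi-model PDB trajectories, and rRNA numbering maps.

The in-memory containers are deliberately small: an :class:`AtomicStructure`
is a flat list of atom records plus an ``(n_atoms, 3)`` coordinate array, with
a residue index keyed by ``(chain_id, residue_number)``.  Author residue
numbers are preserved verbatim — the decoding-center literature mixes
E. coli 16S and yeast 18S numbering, and silent renumbering is how those get
corrupted.  A :class:`Trajectory` is an ordered stack of coordinate frames
over one fixed topology, written to disk as a multi-model PDB file
(one MODEL record per frame).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ResidueView",
    "AtomicStructure",
    "Trajectory",
    "NumberingMap",
    "StructureError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "map_numbering",
    "DEFAULT_NUMBERING_MAP",
]

ResidueId = tuple[str, int]


class StructureError(ValueError):
    """Raised for malformed structures, unreadable files or bad lookups."""


@dataclass(frozen=True)
class Atom:
    """One atom record; coordinates live in the parent structure's array."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str


class ResidueView:
    """Read-only view of one residue of an :class:`AtomicStructure`."""

    def __init__(self, parent: "AtomicStructure", chain_id: str, number: int,
                 indices: np.ndarray):
        self._parent = parent
        self.chain_id = chain_id
        self.number = number
        self.indices = indices

    @property
    def id(self) -> ResidueId:
        return (self.chain_id, self.number)

    @property
    def name(self) -> str:
        return self._parent.atoms[self.indices[0]].residue_name

    @property
    def atom_names(self) -> list[str]:
        return [self._parent.atoms[i].atom_name for i in self.indices]

    def atom_index(self, atom_name: str) -> int:
        for i in self.indices:
            if self._parent.atoms[i].atom_name == atom_name:
                return int(i)
        raise StructureError(
            f"atom {atom_name!r} not found in residue "
            f"{self.chain_id}:{self.number} ({self.name})")

    def has_atom(self, atom_name: str) -> bool:
        return any(self._parent.atoms[i].atom_name == atom_name
                   for i in self.indices)

    def coord(self, atom_name: str) -> np.ndarray:
        return self._parent.coords[self.atom_index(atom_name)]

    @property
    def coords(self) -> np.ndarray:
        return self._parent.coords[self.indices]


class AtomicStructure:
    """Atoms with chain/residue/atom identity plus coordinates for one model.

    Parameters
    ----------
    atoms
        Atom records in file order.
    coords
        ``(n_atoms, 3)`` array of Cartesian coordinates in Å.

    Invariants (checked at construction): coordinates are finite, every atom
    belongs to exactly one residue, and atom names are unique within a
    residue.
    """

    def __init__(self, atoms: Sequence[Atom], coords: np.ndarray):
        self.atoms: list[Atom] = list(atoms)
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coordinate array {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms")
        if len(self.atoms) and not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        self._index: dict[ResidueId, list[int]] = {}
        for i, a in enumerate(self.atoms):
            self._index.setdefault((a.chain_id, a.residue_number), []).append(i)
        self.residue_index: dict[ResidueId, np.ndarray] = {
            k: np.asarray(v, dtype=int) for k, v in self._index.items()}
        for key, idx in self.residue_index.items():
            names = [self.atoms[i].atom_name for i in idx]
            if len(set(names)) != len(names):
                raise StructureError(f"duplicate atom names in residue {key}")

    # -- residue access ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    def residue(self, chain_id: str, number: int) -> ResidueView:
        key = (chain_id, number)
        if key not in self.residue_index:
            raise StructureError(f"no residue {chain_id}:{number}")
        return ResidueView(self, chain_id, number, self.residue_index[key])

    def residues(self) -> Iterator[ResidueView]:
        for (chain_id, number), idx in self.residue_index.items():
            yield ResidueView(self, chain_id, number, idx)

    def chain_residue_ids(self, chain_id: str) -> list[ResidueId]:
        """Residue ids of one chain, in file (author) order."""
        seen: list[ResidueId] = []
        for a in self.atoms:
            key = (a.chain_id, a.residue_number)
            if a.chain_id == chain_id and (not seen or seen[-1] != key):
                if key not in seen:
                    seen.append(key)
        return seen

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def subset(self, residue_ids: Sequence[ResidueId]) -> "AtomicStructure":
        """New structure keeping only the given residues, in original order."""
        wanted = set(residue_ids)
        keep = [i for i, a in enumerate(self.atoms)
                if (a.chain_id, a.residue_number) in wanted]
        return AtomicStructure([self.atoms[i] for i in keep],
                               self.coords[keep])

    def with_coords(self, coords: np.ndarray) -> "AtomicStructure":
        return AtomicStructure(self.atoms, coords)

    def copy(self) -> "AtomicStructure":
        return AtomicStructure(self.atoms, self.coords.copy())


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``frames`` has shape ``(n_frames, n_atoms, 3)``; all frames share the
    topology's atom count and order.  ``frames_per_ns`` carries the sampling
    rate so time axes stay in nanoseconds.
    """

    topology: AtomicStructure
    frames: np.ndarray
    frames_per_ns: float = 100.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
                len(self.topology), 3):
            raise StructureError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{len(self.topology)}-atom topology")
        if not self.frames_per_ns > 0:
            raise StructureError("frames_per_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> AtomicStructure:
        return self.topology.with_coords(self.frames[i])

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frames_per_ns


# -- PDB I/O (via gemmi) ---------------------------------------------------

def _structure_from_gemmi_model(model: gemmi.Model) -> AtomicStructure:
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for res in chain:
            for at in res:
                atoms.append(Atom(chain.name, res.seqid.num, res.name,
                                  at.name, at.element.name))
                coords.append((at.pos.x, at.pos.y, at.pos.z))
    if not atoms:
        raise StructureError("model contains no atoms")
    return AtomicStructure(atoms, np.asarray(coords))


def _read_gemmi(path: str | os.PathLike) -> gemmi.Structure:
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    return st


def read_structure(path: str | os.PathLike,
                   model_index: int | None = None) -> AtomicStructure:
    """Read one model of a PDB file (the first, unless ``model_index`` given).

    Author residue numbers are preserved verbatim.  ``model_index`` is
    0-based over the MODEL records of the file.
    """
    st = _read_gemmi(path)
    idx = 0 if model_index is None else model_index
    if not 0 <= idx < len(st):
        raise IndexError(
            f"model index {idx} out of range: file has {len(st)} model(s)")
    return _structure_from_gemmi_model(st[idx])


def read_trajectory(path: str | os.PathLike,
                    frames_per_ns: float = 100.0) -> Trajectory:
    """Read every model of a multi-model PDB file as trajectory frames."""
    st = _read_gemmi(path)
    topology = _structure_from_gemmi_model(st[0])
    frames = np.empty((len(st), len(topology), 3))
    for fi in range(len(st)):
        frame = _structure_from_gemmi_model(st[fi])
        if len(frame) != len(topology):
            raise StructureError(
                f"model {fi} has {len(frame)} atoms, expected {len(topology)}")
        frames[fi] = frame.coords
    return Trajectory(topology, frames, frames_per_ns=frames_per_ns)


def _to_gemmi(traj: Trajectory) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "ribocar"
    for fi in range(traj.n_frames):
        model = gemmi.Model(fi + 1)
        coords = traj.frames[fi]
        chain: gemmi.Chain | None = None
        res: gemmi.Residue | None = None
        last_key: tuple | None = None
        for i, a in enumerate(traj.topology.atoms):
            if chain is None or chain.name != a.chain_id:
                chain = gemmi.Chain(a.chain_id)
                model.add_chain(chain)
                chain = model[len(model) - 1]
                last_key = None
            key = (a.chain_id, a.residue_number)
            if key != last_key:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                res.het_flag = "A"
                chain.add_residue(res)
                res = chain[len(chain) - 1]
                last_key = key
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*coords[i])
            at.occ = 1.0
            res.add_atom(at)
        st.add_model(model)
    return st


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a trajectory as a multi-model PDB file, one MODEL per frame.

    PDB fixed columns store coordinates at 3 decimals, so a round trip
    through :func:`read_structure` reproduces each frame to 0.001 Å.
    """
    if traj.n_frames == 0:
        raise StructureError("cannot write an empty trajectory")
    st = _to_gemmi(traj)
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string())


def write_structure(s: AtomicStructure, path: str | os.PathLike) -> None:
    """Write a single-model PDB file."""
    write_trajectory(Trajectory(s, s.coords[None, :, :]), path)


# -- residue numbering between E. coli 16S and yeast 18S -------------------

class NumberingMap:
    """Bijective map between E. coli 16S and yeast 18S rRNA landmark numbers.

    The defaults carry the decoding-center landmarks: C1054 (16S) ↔ C1274
    (18S) and A1196 (16S) ↔ A1427 (18S).
    """

    def __init__(self, pairs: Sequence[tuple[int, int, str]]):
        self.pairs = list(pairs)
        self._e2y = {e: y for e, y, _ in self.pairs}
        self._y2e = {y: e for e, y, _ in self.pairs}
        if len(self._e2y) != len(self.pairs) or len(self._y2e) != len(self.pairs):
            raise StructureError("numbering map is not a bijection")

    def ecoli_to_yeast(self, n: int) -> int:
        try:
            return self._e2y[n]
        except KeyError:
            raise KeyError(f"E. coli 16S number {n} not in map") from None

    def yeast_to_ecoli(self, n: int) -> int:
        try:
            return self._y2e[n]
        except KeyError:
            raise KeyError(f"yeast 18S number {n} not in map") from None


DEFAULT_NUMBERING_MAP = NumberingMap([
    (1054, 1274, "C"),
    (1196, 1427, "A"),
    (530, 577, "G"),
])


def map_numbering(n: int, direction: str,
                  numbering_map: NumberingMap | None = None) -> int:
    """Translate an rRNA landmark number between numbering conventions.

    ``direction`` is ``"ecoli_to_yeast"`` or ``"yeast_to_ecoli"``.
    """
    m = numbering_map if numbering_map is not None else DEFAULT_NUMBERING_MAP
    if direction == "ecoli_to_yeast":
        return m.ecoli_to_yeast(n)
    if direction == "yeast_to_ecoli":
        return m.yeast_to_ecoli(n)
    raise ValueError(f"unknown direction {direction!r}")
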