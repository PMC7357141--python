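"""Restrained-subsystem construction around an anchor residue.

A desk-scale reimplementation of the shell-extraction workflow used to cut
a simulable neighborhood out of a whole ribosome: select every residue with
any atom inside a radius of the anchor (by default 40 Å around the G530
nucleotide of the decoding center), merge short gaps between kept segments
so fewer artificial chain breaks are introduced, record a cap at every
remaining artificial terminus, and partition the selection into a
restrained "onion shell" and an unrestrained core.  Nucleotide substitution
grows a new base onto an existing sugar, keeping shared atom coordinates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import chemistry as chem
from . import templates as tpl
from .geometry import GeometryError
from .structure import AtomicStructure, Atom, ResidueId, StructureError

__all__ = [
    "ShellSpec",
    "SubsystemSelection",
    "RestraintMask",
    "SubstitutionSpec",
    "SelectionError",
    "select_shell",
    "build_restraint_mask",
    "substitute_nucleotide",
    "DEFAULT_SHELL_RADIUS_A",
    "DEFAULT_ANCHOR_NUMBER",
    "DEFAULT_RESTRAINT_WEIGHT",
]

DEFAULT_SHELL_RADIUS_A = 40.0
DEFAULT_ANCHOR_NUMBER = 530  # the G530 decoding-center landmark
DEFAULT_RESTRAINT_WEIGHT = 20.0  # kcal/mol/A^2 on the onion shell


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class ShellSpec:
    """Radius-shell selection parameters.

    ``anchor`` is a ``(chain, number)`` residue id, or a bare residue number
    when it is unique across chains.  ``gap_fill_max`` merges kept segments
    of the same chain separated by at most that many intervening residues.
    """

    anchor: ResidueId | int
    radius_A: float = DEFAULT_SHELL_RADIUS_A
    gap_fill_max: int = 10

    def __post_init__(self) -> None:
        if not self.radius_A > 0:
            raise SelectionError("radius_A must be positive")
        if self.gap_fill_max < 0:
            raise SelectionError("gap_fill_max must be >= 0")


@dataclass(frozen=True)
class CapRecord:
    chain_id: str
    residue_number: int
    terminus: str  # "start" | "end"


@dataclass
class SubsystemSelection:
    """Kept residues as per-chain contiguous segments, with break bookkeeping.

    ``break_points`` lists every artificial chain terminus the cut created
    (segment ends that are not native chain termini); ``cap_records``
    mirrors them one-to-one — terminal residues are flagged as caps, no
    ACE/NME atoms are built.
    """

    residue_ids: list[ResidueId]
    segments: dict[str, list[tuple[int, int]]]
    break_points: list[CapRecord]
    cap_records: list[CapRecord]

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in set(self.residue_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def extract(self, s: AtomicStructure) -> AtomicStructure:
        return s.subset(self.residue_ids)


def _resolve_anchor(s: AtomicStructure,
                    anchor: ResidueId | int) -> ResidueId:
    if isinstance(anchor, int):
        hits = [rid for rid in s.residue_index if rid[1] == anchor]
        if not hits:
            raise SelectionError(f"anchor residue number {anchor} not found")
        if len(hits) > 1:
            raise SelectionError(
                f"anchor number {anchor} ambiguous across chains {hits}; "
                "give (chain, number)")
        return hits[0]
    if tuple(anchor) not in s.residue_index:
        raise SelectionError(f"anchor residue {anchor} not found")
    return tuple(anchor)


def select_shell(s: AtomicStructure, spec: ShellSpec) -> SubsystemSelection:
    """Radius-shell residue selection with gap filling and cap bookkeeping.

    A residue is kept iff any of its atoms lies within ``radius_A`` of any
    anchor atom; gaps of at most ``gap_fill_max`` residues between kept
    segments of a chain are then merged in.  Every remaining segment
    terminus that is not a native chain terminus is recorded as a break
    point with a matching cap record.
    """
    anchor = _resolve_anchor(s, spec.anchor)
    anchor_xyz = s.coords[s.residue_index[anchor]]
    tree = cKDTree(s.coords)
    hit_atoms: set[int] = set()
    for xyz in anchor_xyz:
        hit_atoms.update(tree.query_ball_point(xyz, spec.radius_A))
    kept: set[ResidueId] = {
        (s.atoms[i].chain_id, s.atoms[i].residue_number) for i in hit_atoms}
    if not kept:
        raise SelectionError("empty selection: no residue within radius")

    residue_ids: list[ResidueId] = []
    segments: dict[str, list[tuple[int, int]]] = {}
    break_points: list[CapRecord] = []
    for chain in s.chain_ids:
        order = s.chain_residue_ids(chain)
        positions = sorted(i for i, rid in enumerate(order) if rid in kept)
        if not positions:
            continue
        # contiguous runs of kept positions
        runs: list[list[int]] = [[positions[0], positions[0]]]
        for p in positions[1:]:
            if p == runs[-1][1] + 1:
                runs[-1][1] = p
            else:
                runs.append([p, p])
        # merge runs separated by <= gap_fill_max intervening residues
        merged = [runs[0]]
        for run in runs[1:]:
            gap = run[0] - merged[-1][1] - 1
            if gap <= spec.gap_fill_max:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        for lo, hi in merged:
            seg_ids = order[lo:hi + 1]
            residue_ids.extend(seg_ids)
            segments.setdefault(chain, []).append(
                (seg_ids[0][1], seg_ids[-1][1]))
            if lo != 0:
                break_points.append(CapRecord(chain, seg_ids[0][1], "start"))
            if hi != len(order) - 1:
                break_points.append(CapRecord(chain, seg_ids[-1][1], "end"))
    cap_records = list(break_points)
    return SubsystemSelection(residue_ids, segments, break_points,
                              cap_records)


@dataclass
class RestraintMask:
    """Onion-shell restraint mask: restrained/unrestrained residue partition
    plus a positional restraint weight in kcal/mol/Å²."""

    restrained: list[ResidueId]
    unrestrained: list[ResidueId]
    weight: float

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise SelectionError("restraint weight must be positive")
        overlap = set(self.restrained) & set(self.unrestrained)
        if overlap:
            raise SelectionError(f"mask sets overlap: {sorted(overlap)[:5]}")

    def to_json(self) -> str:
        return json.dumps({
            "weight_kcal_per_mol_A2": self.weight,
            "restrained": [[c, n] for c, n in self.restrained],
            "unrestrained": [[c, n] for c, n in self.unrestrained],
        }, indent=1)

    def ambmask(self, selection: SubsystemSelection) -> str:
        """AMBER-style restraintmask over 1-based serial residue positions
        in the selection's residue order."""
        serial = {rid: i + 1 for i, rid in enumerate(selection.residue_ids)}
        nums = sorted(serial[rid] for rid in self.restrained)
        ranges: list[str] = []
        i = 0
        while i < len(nums):
            j = i
            while j + 1 < len(nums) and nums[j + 1] == nums[j] + 1:
                j += 1
            ranges.append(str(nums[i]) if i == j
                          else f"{nums[i]}-{nums[j]}")
            i = j + 1
        return ":" + ",".join(ranges) if ranges else ":"

    def check_buffer(self, selection: SubsystemSelection,
                     protected: Iterable[ResidueId],
                     min_gap: int = 1) -> bool:
        """True iff every protected residue is unrestrained and separated
        from the restrained shell by at least ``min_gap`` sequence
        neighbors within its chain segment."""
        restrained = set(self.restrained)
        by_chain: dict[str, list[ResidueId]] = {}
        for rid in selection.residue_ids:
            by_chain.setdefault(rid[0], []).append(rid)
        for rid in protected:
            if rid in restrained:
                return False
            order = by_chain.get(rid[0], [])
            if rid not in order:
                return False
            pos = order.index(rid)
            lo = max(0, pos - min_gap)
            hi = min(len(order), pos + min_gap + 1)
            if any(r in restrained for r in order[lo:hi]):
                return False
        return True


def build_restraint_mask(sel: SubsystemSelection,
                         core: Iterable[ResidueId],
                         weight: float = DEFAULT_RESTRAINT_WEIGHT,
                         ) -> RestraintMask:
    """Partition a selection into onion shell (restrained) and core.

    ``core`` must be contained in the selection; the rest of the selection
    becomes the restrained shell.  An all-core selection yields an empty
    shell and a warning.
    """
    core_set = {tuple(rid) for rid in core}
    sel_set = set(sel.residue_ids)
    stray = core_set - sel_set
    if stray:
        raise SelectionError(
            f"core residues not in selection: {sorted(stray)[:5]}")
    restrained = [rid for rid in sel.residue_ids if rid not in core_set]
    unrestrained = [rid for rid in sel.residue_ids if rid in core_set]
    if not restrained:
        warnings.warn("restraint mask is empty: core equals the selection",
                      stacklevel=2)
    return RestraintMask(restrained, unrestrained, weight)


# -- nucleotide substitution -----------------------------------------------

_SUGAR_PHOSPHATE = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "O2'", "C1'", "H5'", "H5''", "H4'", "H3'", "HO3'", "H2'",
    "HO2'", "H1'", "HO5'", "HOP2", "HOP3",
}


@dataclass(frozen=True)
class SubstitutionSpec:
    """Replace a nucleotide's base, retaining common atom coordinates."""

    target: ResidueId
    new_base: str
    keep_common_atoms: bool = True

    def __post_init__(self) -> None:
        if chem.normalize_resname(self.new_base) not in chem.NUCLEOTIDES:
            raise SelectionError(
                f"{self.new_base!r} is not a standard ribonucleotide")


def _glycosidic_anchors(resname: str) -> tuple[str, str]:
    """(glycosidic N, adjacent ring atom) for a base type."""
    if chem.normalize_resname(resname) in chem.PURINES:
        return "N9", "C4"
    return "N1", "C2"


def _base_plane_normal(res_view, resname: str) -> np.ndarray:
    ring = chem.RING_ATOMS[chem.normalize_resname(resname)]
    pts = np.array([res_view.coord(n) for n in ring])
    return tpl.plane_normal(pts)


def substitute_nucleotide(
        s: AtomicStructure, spec: SubstitutionSpec,
        templates: Mapping[str, AtomicStructure] | None = None,
        ) -> AtomicStructure:
    """Swap the base of one nucleotide, growing new atoms from an idealized
    template superposed on the glycosidic frame.

    Atoms shared by the old and new base (by name), and the whole
    sugar-phosphate backbone, keep their coordinates; atoms unique to the
    new base are placed from the template aligned on (glycosidic N, C1',
    adjacent ring atom), which preserves the base-plane orientation relative
    to the backbone.  A plane-normal rotation above 5° is rejected.
    """
    rid = tuple(spec.target)
    if rid not in s.residue_index:
        raise StructureError(f"no residue {rid}")
    res = s.residue(*rid)
    old_name = chem.normalize_resname(res.name)
    if old_name not in chem.NUCLEOTIDES:
        raise TypeError(
            f"residue {rid} ({res.name}) is not a standard ribonucleotide")
    new_name = chem.normalize_resname(spec.new_base)

    old_gn, old_ring = _glycosidic_anchors(old_name)
    for a in (old_gn, "C1'", old_ring):
        if not res.has_atom(a):
            raise GeometryError(
                f"residue {rid} lacks anchor atom {a!r} for substitution")

    if templates is not None and new_name in templates:
        template = templates[new_name]
    else:
        template = tpl.ideal_residue(new_name)
    t_rid = (template.atoms[0].chain_id, template.atoms[0].residue_number)
    t_res = template.residue(*t_rid)
    new_gn, new_ring = _glycosidic_anchors(new_name)

    moving = np.array([t_res.coord(new_gn), t_res.coord("C1'"),
                       t_res.coord(new_ring)])
    target = np.array([res.coord(old_gn), res.coord("C1'"),
                       res.coord(old_ring)])
    rot, t = tpl.kabsch(moving, target)
    placed = template.with_coords(template.coords @ rot.T + t)
    p_res = placed.residue(*t_rid)

    old_names = set(res.atom_names)
    template_names = list(p_res.atom_names)
    if old_name == new_name:
        keep_names = list(res.atom_names)
        new_only: list[str] = []
    else:
        keep_names = [n for n in res.atom_names
                      if n in _SUGAR_PHOSPHATE or n in template_names]
        new_only = [n for n in template_names
                    if n not in old_names and n not in _SUGAR_PHOSPHATE]

    new_atoms: list[Atom] = []
    new_coords: list[np.ndarray] = []
    for n in keep_names:
        i = res.atom_index(n)
        a = s.atoms[i]
        new_atoms.append(Atom(a.chain_id, a.residue_number, new_name,
                              a.atom_name, a.element))
        new_coords.append(s.coords[i])
    for n in new_only:
        i = p_res.atom_index(n)
        a = placed.atoms[i]
        new_atoms.append(Atom(rid[0], rid[1], new_name, n, a.element))
        new_coords.append(placed.coords[i])

    # rebuild full structure with the residue replaced in place
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    inserted = False
    res_idx = set(int(i) for i in s.residue_index[rid])
    for i, a in enumerate(s.atoms):
        if i in res_idx:
            if not inserted:
                atoms.extend(new_atoms)
                coords.extend(new_coords)
                inserted = True
            continue
        atoms.append(a)
        coords.append(s.coords[i])
    out = AtomicStructure(atoms, np.asarray(coords))

    normal_old = _base_plane_normal(res, old_name)
    normal_new = _base_plane_normal(out.residue(*rid), new_name)
    cosang = abs(float(np.dot(normal_old, normal_new)))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if angle > 5.0:
        raise SelectionError(
            f"base plane rotated {angle:.1f} deg > 5 deg during substitution")
    return out
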