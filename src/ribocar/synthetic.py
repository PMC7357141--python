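"""Synthetic fixtures with known ground truth.

Generates idealized base pairs (Watson–Crick, trans Watson–Crick/Hoogsteen,
G:U wobble), stacked arrangements at controlled rise, a miniature
decoding-center fixture presenting the CAR surface (C1054, A1196, an
arginine guanidinium) to an A-site codon–anticodon duplex and a +1 codon,
and scripted multi-frame trajectories with per-frame bond formation/breakage
plus Gaussian coordinate noise.

These fixtures emulate the geometry the analysis code measures — H-bond
edges, stacking rises, bond schedules — not the energetics of a force
field: noise is uncorrelated per atom per frame, and "broken" pairs are
rigid displacements beyond 6 Å, well outside both the H-bond cutoff and the
stacked/unstacked ambiguity band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from . import chemistry as chem
from . import geometry as geom
from . import templates as tpl
from .structure import AtomicStructure, ResidueId, Trajectory

__all__ = [
    "PairGeometrySpec",
    "TrajectorySpec",
    "SpecError",
    "make_pair",
    "make_stack",
    "make_mrna_strand",
    "make_car_fixture",
    "make_trajectory",
    "strip_hydrogens",
    "merge_structures",
    "CAR_FIXTURE_RESIDUES",
]


class SpecError(ValueError):
    """Unsupported or inconsistent fixture specification."""


# Defining H-bonds per pair kind, in canonical base order.  Entries are
# (donor_side, donor_heavy, acceptor_heavy) with side 0 = first base.
_PAIR_BONDS: dict[tuple[str, str, str], list[tuple[int, str, str]]] = {
    # classic three-bond G:C Watson-Crick pair
    ("wc", "G", "C"): [(1, "N4", "O6"), (0, "N1", "N3"), (0, "N2", "O2")],
    ("wc", "A", "U"): [(0, "N6", "O4"), (1, "N3", "N1")],
    # reverse Hoogsteen: adenine Hoogsteen face to pyrimidine WC face
    ("trans_wc_hoogsteen", "A", "C"): [(0, "N6", "N3"), (1, "N4", "N7")],
    ("trans_wc_hoogsteen", "A", "U"): [(0, "N6", "O2"), (1, "N3", "N7")],
    ("wobble", "G", "U"): [(1, "N3", "O6"), (0, "N1", "O2")],
}


@dataclass(frozen=True)
class PairGeometrySpec:
    """An idealized two-base arrangement.

    ``kind`` is ``"wc"``, ``"trans_wc_hoogsteen"`` or ``"wobble"``;
    ``distance_A`` is the target donor–acceptor heavy-atom distance for every
    defining bond (pairs built beyond the 3.0 Å detection cutoff come out
    bond-free by construction).
    """

    kind: str
    base_a: str
    base_b: str
    distance_A: float = 2.9


@dataclass
class TrajectorySpec:
    """Scripted trajectory: frame count, sampling rate, noise and a per-pair
    bond schedule.  ``schedule`` maps a residue-id pair to the frame ranges
    ``[(start, stop), ...)`` during which the pair is *formed*; outside those
    ranges the second residue of the pair is displaced to ≥ 6 Å separation.
    """

    n_frames: int
    frames_per_ns: float = 100.0
    noise_sigma_A: float = 0.0
    seed: int = 0
    schedule: dict[tuple[ResidueId, ResidueId],
                   tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_frames <= 0:
            raise SpecError("n_frames must be positive")
        for pair, ranges in self.schedule.items():
            for start, stop in ranges:
                if not (0 <= start < stop <= self.n_frames):
                    raise SpecError(
                        f"schedule range ({start}, {stop}) for {pair} outside "
                        f"frame count {self.n_frames}")

    def formed(self, pair: tuple[ResidueId, ResidueId], frame: int) -> bool:
        ranges = self.schedule.get(pair)
        if ranges is None:
            return True
        return any(start <= frame < stop for start, stop in ranges)

    def formed_mask(self, pair: tuple[ResidueId, ResidueId]) -> np.ndarray:
        return np.array([self.formed(pair, f) for f in range(self.n_frames)])


def merge_structures(*parts: AtomicStructure) -> AtomicStructure:
    atoms = [a for p in parts for a in p.atoms]
    coords = np.concatenate([p.coords for p in parts]) if parts else \
        np.empty((0, 3))
    return AtomicStructure(atoms, coords)


def strip_hydrogens(s: AtomicStructure) -> AtomicStructure:
    keep = [i for i, a in enumerate(s.atoms) if a.element.upper() != "H"]
    return AtomicStructure([s.atoms[i] for i in keep], s.coords[keep])


# -- pair construction -----------------------------------------------------

def _lookup_bonds(kind: str, base_a: str,
                  base_b: str) -> list[tuple[int, str, str]]:
    key = (kind, base_a, base_b)
    if key in _PAIR_BONDS:
        return _PAIR_BONDS[key]
    swapped = (kind, base_b, base_a)
    if swapped in _PAIR_BONDS:
        return [(1 - side, d, a) for side, d, a in _PAIR_BONDS[swapped]]
    raise SpecError(f"unsupported pair type {kind} {base_a}:{base_b}")


def _engaged_atoms(bonds: Sequence[tuple[int, str, str]],
                   side: int) -> list[tuple[str, str]]:
    """(atom, role) list for one side of the bond table."""
    out = []
    for s, donor, acceptor in bonds:
        if s == side:
            out.append((donor, "donor"))
        else:
            out.append((acceptor, "acceptor"))
    return out


def _pair_coords_builder(res_a: AtomicStructure, res_b0: AtomicStructure,
                         bonds, target_d: float):
    """Optimize the in-plane rigid placement of base B against fixed base A.

    Base A sits in its canonical frame (ring COM at origin, plane z = 0).
    Base B is pre-oriented likewise, optionally flipped about x, then an
    in-plane rotation/translation is fit so every defining donor–acceptor
    distance hits ``target_d`` with the donor hydrogen pointing at the
    acceptor.  Deterministic multi-start least squares.
    """
    rid_a = (res_a.atoms[0].chain_id, res_a.atoms[0].residue_number)
    rid_b = (res_b0.atoms[0].chain_id, res_b0.atoms[0].residue_number)
    va = res_a.residue(*rid_a)

    def side_points(structure, rid, atoms):
        res = structure.residue(*rid)
        return np.array([res.coord(a) for a in atoms])

    edge_a_atoms = [a for a, _ in _engaged_atoms(bonds, 0)]
    edge_b_atoms = [a for a, _ in _engaged_atoms(bonds, 1)]
    e_a = side_points(res_a, rid_a, edge_a_atoms).mean(axis=0)
    dir_a = e_a.copy()
    dir_a[2] = 0.0
    dir_a /= max(np.linalg.norm(dir_a), 1e-9)

    name_b = chem.normalize_resname(res_b0.atoms[0].residue_name)
    donor_h = chem.DONOR_HYDROGENS.get(name_b, {})
    name_a = chem.normalize_resname(res_a.atoms[0].residue_name)
    donor_h_a = chem.DONOR_HYDROGENS.get(name_a, {})

    def transformed(coords_b, theta, tx, ty):
        return coords_b @ tpl.rot_z(theta).T + np.array([tx, ty, 0.0])

    def build_struct(coords_b):
        return merge_structures(res_a, res_b0.with_coords(coords_b))

    heavy_a = np.array([i for i, at in enumerate(res_a.atoms)
                        if at.element.upper() != "H"])
    heavy_b = np.array([i for i, at in enumerate(res_b0.atoms)
                        if at.element.upper() != "H"])
    bonded = set()
    for side, donor, acceptor in bonds:
        pa, pb = (donor, acceptor) if side == 0 else (acceptor, donor)
        ia = next(i for i in heavy_a if res_a.atoms[i].atom_name == pa)
        ib = next(i for i in heavy_b if res_b0.atoms[i].atom_name == pb)
        bonded.add((int(ia), int(ib)))

    def residuals(p, coords_b):
        c = transformed(coords_b, *p)
        s = build_struct(c)
        vb = s.residue(*rid_b)
        res = []
        for side, donor, acceptor in bonds:
            if side == 0:
                d_res, a_res = va, vb
                hs = donor_h_a.get(donor, ())
            else:
                d_res, a_res = vb, va
                hs = donor_h.get(donor, ())
            d_xyz = d_res.coord(donor)
            a_xyz = a_res.coord(acceptor)
            dist = np.linalg.norm(d_xyz - a_xyz)
            res.append(dist - target_d)
            best = 0.0
            for h in hs:
                if d_res.has_atom(h):
                    best = max(best, geom._angle_deg(
                        d_xyz, d_res.coord(h), a_xyz))
            res.append(max(0.0, 155.0 - best) / 20.0)
        ring_sep = np.linalg.norm(tpl.ring_com(s, *rid_b)
                                  - tpl.ring_com(s, *rid_a))
        res.append(max(0.0, 4.8 - ring_sep))
        # steric clearance: non-bonded heavy atoms of the two residues must
        # not interpenetrate (keeps the optimizer off mis-registered minima)
        d = np.linalg.norm(res_a.coords[heavy_a][:, None, :]
                           - c[heavy_b][None, :, :], axis=2)
        clash = np.maximum(0.0, 2.7 - d)
        for ia, ib in bonded:
            clash[np.searchsorted(heavy_a, ia),
                  np.searchsorted(heavy_b, ib)] = 0.0
        res.append(float(clash.sum()) * 3.0)
        return res

    best_cost = np.inf
    best_coords = None
    for flip in (True, False):
        coords_b = res_b0.coords @ tpl.rot_x(np.pi).T if flip \
            else res_b0.coords
        vb0 = res_b0.with_coords(coords_b).residue(*rid_b)
        e_b = np.array([vb0.coord(a) for a in edge_b_atoms]).mean(axis=0)
        target_pt = e_a + dir_a * max(target_d, 0.5)
        for theta0 in np.linspace(0.0, 2 * np.pi, 8, endpoint=False):
            e_b_rot = tpl.rot_z(theta0) @ e_b
            t0 = target_pt - e_b_rot
            sol = least_squares(residuals, [theta0, t0[0], t0[1]],
                                args=(coords_b,), method="lm",
                                max_nfev=400)
            if sol.cost < best_cost:
                best_cost = sol.cost
                best_coords = transformed(coords_b, *sol.x)
    return build_struct(best_coords)


def _build_pair(kind: str, a: tuple[str, str, int], b: tuple[str, str, int],
                distance_A: float) -> AtomicStructure:
    name_a, chain_a, num_a = a
    name_b, chain_b, num_b = b
    bonds = _lookup_bonds(kind, chem.normalize_resname(name_a),
                          chem.normalize_resname(name_b))
    res_a = tpl.oriented_residue(name_a, chain_a, num_a)
    res_b = tpl.oriented_residue(name_b, chain_b, num_b)
    return _pair_coords_builder(res_a, res_b, bonds, distance_A)


def _verify_pair(s: AtomicStructure, kind: str, rid_a: ResidueId,
                 rid_b: ResidueId, bonds) -> None:
    events = geom.detect_hbonds(s)
    found = {(ev.donor_residue, ev.donor_atom,
              ev.acceptor_residue, ev.acceptor_atom) for ev in events}
    for side, donor, acceptor in bonds:
        want = ((rid_a, donor, rid_b, acceptor) if side == 0
                else (rid_b, donor, rid_a, acceptor))
        if want not in found:
            raise SpecError(
                f"constructed {kind} pair failed to form bond {want}")


def make_pair(spec: PairGeometrySpec, chain_a: str = "A",
              chain_b: str = "B") -> AtomicStructure:
    """Build an idealized two-residue base pair.

    The two residues land on chains ``chain_a``/``chain_b``, both numbered 1,
    with the first base in its canonical frame.  For formed geometries
    (target distance under the 3.0 Å detection cutoff) the construction is
    verified to reproduce the pair's defining H-bond list under
    :func:`ribocar.geometry.detect_hbonds` at default cutoffs.
    """
    bonds = _lookup_bonds(spec.kind, chem.normalize_resname(spec.base_a),
                          chem.normalize_resname(spec.base_b))
    s = _build_pair(spec.kind, (spec.base_a, chain_a, 1),
                    (spec.base_b, chain_b, 1), spec.distance_A)
    if spec.distance_A < geom.DEFAULT_DIST_CUTOFF_A:
        _verify_pair(s, spec.kind, (chain_a, 1), (chain_b, 1), bonds)
    return s


def make_stack(base_a: str, base_b: str, rise: float = 3.9,
               twist_deg: float = 36.0) -> AtomicStructure:
    """Two bases stacked coaxially: ring mass centers exactly ``rise`` apart,
    rotated ``twist_deg`` about the stacking axis."""
    res_a = tpl.oriented_residue(base_a, "A", 1)
    res_b = tpl.oriented_residue(base_b, "B", 1)
    res_b = tpl.apply_rigid(res_b, tpl.rot_z(np.radians(twist_deg)),
                            np.array([0.0, 0.0, rise]))
    return merge_structures(res_a, res_b)


def make_mrna_strand(seq: str, chain_id: str = "M", start_number: int = 1,
                     rise: float = 3.8,
                     twist_deg: float = 32.0) -> AtomicStructure:
    """A single-chain stacked column of nucleotides (a schematic helix).

    Used as the generic single-chain fixture (shell selection, substitution,
    RMSD) — base planes are parallel, ring centers on the z axis at
    ``rise`` spacing.
    """
    parts = []
    for i, base in enumerate(seq):
        if base not in "ACGU":
            raise SpecError(f"invalid RNA base {base!r}")
        res = tpl.oriented_residue(base, chain_id, start_number + i)
        res = tpl.apply_rigid(res, tpl.rot_z(np.radians(i * twist_deg)),
                              np.array([0.0, 0.0, i * rise]))
        parts.append(res)
    return merge_structures(*parts)


# -- the miniature decoding-center fixture ---------------------------------

CAR_FIXTURE_RESIDUES = {
    "C1054": ("R", 1054),
    "A1196": ("R", 1196),
    "R146": ("P", 146),
    "wobble": ("T", 34),
    "anticodon": (("T", 36), ("T", 35), ("T", 34)),
    "asite_codon": (("M", 4), ("M", 5), ("M", 6)),
    "plus1_codon": (("M", 7), ("M", 8), ("M", 9)),
}


def _place(s: AtomicStructure, twist_deg: float, z: float) -> AtomicStructure:
    return tpl.apply_rigid(s, tpl.rot_z(np.radians(twist_deg)),
                           np.array([0.0, 0.0, z]))


def _facing_residue(name: str, chain_id: str, number: int,
                    target_com: np.ndarray, gap: float,
                    plane_z: float, azimuth_deg: float) -> AtomicStructure:
    """Place a base in a stacking plane with its WC edge pointing back at a
    target point, ``gap`` Å away — close enough to look poised, too far to
    bond (used for the purine-clash and non-cognate cases)."""
    res = tpl.oriented_residue(name, chain_id, number)
    res = tpl.apply_rigid(res, tpl.rot_x(np.pi), np.zeros(3))
    theta = np.radians(azimuth_deg + 180.0)
    rot = tpl.rot_z(theta)
    res = tpl.apply_rigid(res, rot, np.zeros(3))
    name_n = chem.normalize_resname(name)
    rid = (chain_id, number)
    edge = chem.edge_atoms(name_n, "WC")
    view = res.residue(*rid)
    e = np.mean([view.coord(a) for a in edge], axis=0)
    direction = np.array([np.cos(np.radians(azimuth_deg)),
                          np.sin(np.radians(azimuth_deg)), 0.0])
    desired = target_com + direction * gap
    shift = desired - e
    shift[2] = plane_z - e[2]
    return tpl.apply_rigid(res, np.eye(3), shift)


def make_car_fixture(plus1_codon: str = "GCU",
                     rise: float = 3.8) -> AtomicStructure:
    """Miniature CAR decoding-center neighborhood with a configurable +1 codon.

    Layout (stacking axis = z, step = ``rise``, default 3.8 Å so all stack
    rises sit in the observed 3.5–4.0 Å band):

    * A-site codon CCU (chain M, 4–6) Watson–Crick paired to a GGG anticodon
      (chain T, 36–34) with a G:U wobble at position 3;
    * the wobble G (T:34) stacked under C1054 (chain R);
    * C1054 Watson–Crick paired to +1 position 1 when that base is G;
    * A1196 stacked on C1054, presenting its Hoogsteen edge to +1 position 2
      (trans WC/Hoogsteen pair for C or U; purines are parked with their
      edge ≥ 4 Å away, modelling the steric clash as increased separation);
    * an arginine guanidinium group (chain P, 146) stacked on A1196.
    """
    codon = plus1_codon.upper().replace("T", "U")
    if len(codon) != 3 or any(b not in "ACGU" for b in codon):
        raise SpecError(f"invalid +1 codon {plus1_codon!r}")

    parts: list[AtomicStructure] = []
    twist = 32.0

    # codon-anticodon duplex, planes below the CAR column
    duplex = [
        ("wc", ("G", "T", 36), ("C", "M", 4), -3 * rise, -3 * twist),
        ("wc", ("G", "T", 35), ("C", "M", 5), -2 * rise, -2 * twist),
        ("wobble", ("G", "T", 34), ("U", "M", 6), -1 * rise, -1 * twist),
    ]
    for kind, a, b, z, tw in duplex:
        parts.append(_place(_build_pair(kind, a, b, 2.9), tw, z))

    # C1054 plane: pair with G1 when cognate, otherwise park the base
    if codon[0] == "G":
        parts.append(_place(
            _build_pair("wc", ("C", "R", 1054), (codon[0], "M", 7), 2.9),
            0.0, 0.0))
    else:
        parts.append(_place(tpl.oriented_residue("C", "R", 1054), 0.0, 0.0))
        merged = merge_structures(*parts)
        com = geom.edge_com(merged, ("R", 1054), "WC")
        parts.append(_facing_residue(codon[0], "M", 7, com, 6.5, 0.0, 0.0))

    # A1196 plane: Hoogsteen face toward +1 position 2
    z2 = rise
    if codon[1] in "CU":
        parts.append(_place(
            _build_pair("trans_wc_hoogsteen", ("A", "R", 1196),
                        (codon[1], "M", 8), 2.9), twist, z2))
    else:
        parts.append(_place(tpl.oriented_residue("A", "R", 1196), twist, z2))
        merged = merge_structures(*parts)
        com = geom.edge_com(merged, ("R", 1196), "Hoogsteen")
        az = twist
        parts.append(_facing_residue(codon[1], "M", 8, com, 4.2, z2, az))

    # guanidinium plane
    parts.append(_place(tpl.oriented_residue("ARG", "P", 146),
                        2 * twist, 2 * rise))

    # +1 position 3, stacked above position 2
    merged = merge_structures(*parts)
    com2 = tpl.ring_com(merged, "M", 8)
    res9 = tpl.oriented_residue(codon[2], "M", 9)
    res9 = tpl.apply_rigid(res9, tpl.rot_z(np.radians(2 * twist)),
                           com2 + np.array([0.0, 0.0, rise]))
    parts.append(res9)

    merged = merge_structures(*parts)
    return _reorder_chains(merged)


def _reorder_chains(s: AtomicStructure) -> AtomicStructure:
    """Group atoms chain by chain (keeps multi-part assemblies PDB-clean)."""
    order: list[int] = []
    for cid in sorted(set(a.chain_id for a in s.atoms)):
        members = [(a.residue_number, i) for i, a in enumerate(s.atoms)
                   if a.chain_id == cid]
        members.sort(key=lambda t: (t[0], t[1]))
        order.extend(i for _, i in members)
    return AtomicStructure([s.atoms[i] for i in order], s.coords[order])


# -- scripted trajectories -------------------------------------------------

def _push_vector(base: AtomicStructure, pair: tuple[ResidueId, ResidueId],
                 min_sep: float = 6.0) -> np.ndarray:
    """Displacement for the pair's second residue guaranteeing ≥ min_sep
    separation between the two ring mass centers."""
    rid_a, rid_b = pair
    com_a = tpl.ring_com(base, *rid_a)
    com_b = tpl.ring_com(base, *rid_b)
    axis = com_b - com_a
    norm = np.linalg.norm(axis)
    if norm < 1e-6:
        axis, norm = np.array([1.0, 0.0, 0.0]), 1.0
    unit = axis / norm
    magnitude = min_sep + 1.0
    while np.linalg.norm(com_b + magnitude * unit - com_a) < min_sep:
        magnitude *= 1.5
    return magnitude * unit


def make_trajectory(base: AtomicStructure,
                    spec: TrajectorySpec) -> Trajectory:
    """Scripted multi-frame trajectory over a fixture.

    Each frame starts from the base geometry; pairs scheduled *broken* in
    that frame have their second residue rigidly displaced beyond 6 Å;
    i.i.d. Gaussian noise of ``noise_sigma_A`` is then added to every
    coordinate.  The same seed reproduces the trajectory exactly.  The
    schedule, seed and noise level are recorded in the trajectory metadata.
    """
    spec.validate()
    for pair in spec.schedule:
        for rid in pair:
            if rid not in base.residue_index:
                raise SpecError(f"schedule references unknown residue {rid}")
    pushes = {pair: _push_vector(base, pair) for pair in spec.schedule}
    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, len(base), 3))
    for f in range(spec.n_frames):
        coords = base.coords.copy()
        for pair, push in pushes.items():
            if not spec.formed(pair, f):
                idx = base.residue_index[pair[1]]
                coords[idx] += push
        if spec.noise_sigma_A > 0:
            coords += rng.normal(0.0, spec.noise_sigma_A, coords.shape)
        frames[f] = coords
    metadata = {
        "seed": spec.seed,
        "noise_sigma_A": spec.noise_sigma_A,
        "schedule": {pair: tuple(ranges)
                     for pair, ranges in spec.schedule.items()},
        "spec": spec,
    }
    return Trajectory(base, frames, frames_per_ns=spec.frames_per_ns,
                      metadata=metadata)
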