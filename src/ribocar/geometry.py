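"""Per-frame geometry of the decoding-center neighborhood.

Implements the trajectory observables used throughout the analysis:

* hydrogen-bond detection with the cpptraj-style criterion — donor-to-
  acceptor heavy-atom distance < 3.0 Å and donor–H–acceptor angle ≥ 135°
  (hydrogen at the vertex);
* assignment of each bond to Watson–Crick / Hoogsteen / guanidinium edges;
* edge-to-edge distances between mass-weighted centers of the donor and
  acceptor heavy atoms of each edge, including the guanidinium minimum-edge
  rule (the smaller of the {NE,NH1} and {NE,NH2} center distances);
* base-stacking distances between ring-atom centers of mass;
* backbone RMSD after least-squares superposition;
* time-course extraction at a stride and 1-ns binning.

All detection requires explicit hydrogens; a structure whose donors carry no
hydrogens raises :class:`MissingHydrogenError` rather than silently
reporting nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import chemistry as chem
from .structure import AtomicStructure, ResidueId, ResidueView, Trajectory

__all__ = [
    "GeometryError",
    "MissingHydrogenError",
    "Donor",
    "Acceptor",
    "HBondEvent",
    "ClassifiedHBond",
    "MetricSeries",
    "BinnedSeries",
    "PairSpec",
    "GuanidiniumDistance",
    "enumerate_donors",
    "enumerate_acceptors",
    "detect_hbonds",
    "classify_edge",
    "edge_pair_counts",
    "edge_distance",
    "guanidinium_edge_distance",
    "stacking_distance",
    "backbone_rmsd",
    "series_extract",
    "bin_series",
    "DEFAULT_DIST_CUTOFF_A",
    "DEFAULT_ANGLE_CUTOFF_DEG",
    "DEFAULT_STACKING_CUTOFF_A",
]

DEFAULT_DIST_CUTOFF_A = 3.0
DEFAULT_ANGLE_CUTOFF_DEG = 135.0
# stacked readings sit between 3 and 4 Å, unstacked above 5 Å; the reporting
# boundary is the midpoint of the ambiguous band and is configurable
DEFAULT_STACKING_CUTOFF_A = 4.5


class GeometryError(ValueError):
    """Missing atoms or otherwise unusable geometry."""


class MissingHydrogenError(GeometryError):
    """H-bond detection was asked for on donors with no explicit hydrogens."""


class Donor(NamedTuple):
    residue: ResidueId
    resname: str
    heavy: str
    hydrogens: tuple[str, ...]


class Acceptor(NamedTuple):
    residue: ResidueId
    resname: str
    atom: str


@dataclass(frozen=True)
class HBondEvent:
    """One detected hydrogen bond in one frame."""

    frame: int
    donor_residue: ResidueId
    donor_resname: str
    donor_atom: str
    hydrogen: str
    acceptor_residue: ResidueId
    acceptor_resname: str
    acceptor_atom: str
    distance_A: float
    angle_deg: float

    @property
    def pair(self) -> tuple[ResidueId, ResidueId]:
        return tuple(sorted((self.donor_residue, self.acceptor_residue)))


@dataclass(frozen=True)
class ClassifiedHBond:
    event: HBondEvent
    donor_edge: str
    acceptor_edge: str


class GuanidiniumDistance(NamedTuple):
    distance_A: float
    branch: str  # "NE,NH1" or "NE,NH2"


@dataclass
class MetricSeries:
    """A named per-frame observable for one residue pair."""

    metric: str
    pair_id: str
    values: np.ndarray
    frames_per_ns: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frames_per_ns

    def mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class BinnedSeries:
    metric: str
    pair_id: str
    bin_means: np.ndarray
    bin_counts: np.ndarray
    bin_ns: float
    last_bin_partial: bool


@dataclass(frozen=True)
class PairSpec:
    """Which residue pair to follow, and along which edges.

    ``edge_a`` / ``edge_b`` are ``"WC"``, ``"Hoogsteen"``, ``"guanidinium"``
    or ``None`` (whole residue, used for off-edge bookkeeping).
    """

    res_a: ResidueId
    res_b: ResidueId
    edge_a: str | None = "WC"
    edge_b: str | None = "WC"
    metrics: tuple[str, ...] = ("hbond_count", "distance")

    @property
    def pair_id(self) -> str:
        ea = self.edge_a or "all"
        eb = self.edge_b or "all"
        return (f"{self.res_a[0]}:{self.res_a[1]}({ea})-"
                f"{self.res_b[0]}:{self.res_b[1]}({eb})")


# -- donor / acceptor enumeration -----------------------------------------

def _edge_restriction(resname: str, edge: str | None) -> set[str] | None:
    if edge is None:
        return None
    return set(chem.edge_atoms(resname, edge))


def enumerate_donors(s: AtomicStructure,
                     residues: Iterable[ResidueId] | None = None,
                     edge: str | None = None) -> list[Donor]:
    """All donor heavy atoms (with their present hydrogens) of a structure.

    Donors whose hydrogens are absent from the file are skipped (a
    phosphodiester O5' has no HO5'); :func:`detect_hbonds` raises if *no*
    donor in the whole set has a hydrogen.
    """
    out: list[Donor] = []
    ids = list(residues) if residues is not None else list(s.residue_index)
    for rid in ids:
        res = s.residue(*rid)
        name = chem.normalize_resname(res.name)
        table = chem.DONOR_HYDROGENS.get(name)
        if table is None:
            continue
        allowed = _edge_restriction(name, edge)
        present = set(res.atom_names)
        for heavy, hnames in table.items():
            if heavy not in present:
                continue
            if allowed is not None and heavy not in allowed:
                continue
            hs = tuple(h for h in hnames if h in present)
            out.append(Donor(rid, name, heavy, hs))
    return out


def enumerate_acceptors(s: AtomicStructure,
                        residues: Iterable[ResidueId] | None = None,
                        edge: str | None = None) -> list[Acceptor]:
    out: list[Acceptor] = []
    ids = list(residues) if residues is not None else list(s.residue_index)
    for rid in ids:
        res = s.residue(*rid)
        name = chem.normalize_resname(res.name)
        table = chem.ACCEPTORS.get(name)
        if table is None:
            continue
        allowed = _edge_restriction(name, edge)
        present = set(res.atom_names)
        for atom in table:
            if atom not in present:
                continue
            if allowed is not None and atom not in allowed:
                continue
            out.append(Acceptor(rid, name, atom))
    return out


# -- hydrogen-bond detection -----------------------------------------------

def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u = a - vertex
    v = b - vertex
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def detect_hbonds(frame: AtomicStructure,
                  donors: Sequence[Donor] | None = None,
                  acceptors: Sequence[Acceptor] | None = None,
                  dist_cutoff_A: float = DEFAULT_DIST_CUTOFF_A,
                  angle_cutoff_deg: float = DEFAULT_ANGLE_CUTOFF_DEG,
                  frame_index: int = 0) -> list[HBondEvent]:
    """Detect hydrogen bonds in one frame.

    A bond is reported iff the donor-heavy-to-acceptor distance is strictly
    below ``dist_cutoff_A`` and, for at least one hydrogen attached to the
    donor, the donor–H–acceptor angle is at least ``angle_cutoff_deg``
    (hydrogen at the vertex).  Intra-residue pairs are excluded.  When the
    donor/acceptor lists are omitted they are enumerated from the standard
    chemistry tables over the whole structure.
    """
    if donors is None:
        donors = enumerate_donors(frame)
    if acceptors is None:
        acceptors = enumerate_acceptors(frame)
    if not donors or not acceptors:
        return []
    if all(len(d.hydrogens) == 0 for d in donors):
        raise MissingHydrogenError(
            "no donor carries an explicit hydrogen; add hydrogens before "
            "H-bond detection")
    donors = [d for d in donors if d.hydrogens]

    acc_xyz = np.empty((len(acceptors), 3))
    acc_res: list[ResidueView] = []
    for i, acc in enumerate(acceptors):
        res = frame.residue(*acc.residue)
        acc_res.append(res)
        acc_xyz[i] = res.coord(acc.atom)
    tree = cKDTree(acc_xyz)

    events: list[HBondEvent] = []
    for don in donors:
        res = frame.residue(*don.residue)
        d_xyz = res.coord(don.heavy)
        h_xyz = [res.coord(h) for h in don.hydrogens]
        for j in tree.query_ball_point(d_xyz, dist_cutoff_A):
            acc = acceptors[j]
            if acc.residue == don.residue:
                continue
            dist = float(np.linalg.norm(acc_xyz[j] - d_xyz))
            if not dist < dist_cutoff_A:
                continue
            best_angle = -1.0
            best_h = None
            for hname, hx in zip(don.hydrogens, h_xyz):
                ang = _angle_deg(d_xyz, hx, acc_xyz[j])
                if ang > best_angle:
                    best_angle = ang
                    best_h = hname
            if best_angle >= angle_cutoff_deg:
                events.append(HBondEvent(
                    frame_index, don.residue, don.resname, don.heavy,
                    best_h, acc.residue, acc.resname, acc.atom,
                    dist, best_angle))
    return events


# -- edge classification ---------------------------------------------------

_EDGE_PREFERENCE = ("WC", "Hoogsteen", "guanidinium")


def _possible_edges(resname: str, atom: str, role: str) -> set[str]:
    name = chem.normalize_resname(resname)
    out: set[str] = set()
    for edge in ("WC", "Hoogsteen", "guanidinium"):
        try:
            table = chem.edge_atoms(name, edge)
        except KeyError:
            continue
        if table.get(atom) == role:
            out.add(edge)
    return out


def _pick_edge(candidates: list[set[str]]) -> list[str]:
    """Assign an edge label to each atom's candidate set, preferring one
    consistent edge for the whole residue; ties break toward Watson-Crick."""
    nonempty = [c for c in candidates if c]
    labels: list[str] = []
    common: set[str] = set.intersection(*nonempty) if nonempty else set()
    chosen = next((e for e in _EDGE_PREFERENCE if e in common), None)
    for cand in candidates:
        if not cand:
            labels.append("off-edge")
        elif chosen is not None:
            labels.append(chosen)
        else:
            labels.append(next(e for e in _EDGE_PREFERENCE if e in cand))
    return labels


def classify_edge(events: Sequence[HBondEvent]) -> list[ClassifiedHBond]:
    """Assign each H-bond's donor and acceptor atom to a base-pair edge.

    Atoms shared between edges (adenine N6 sits on both the WC and the
    Hoogsteen face) are disambiguated per residue pair: if a single edge
    explains every bonded atom of that residue within the pair, it wins;
    otherwise atoms are labelled independently, preferring WC.  Atoms on no
    edge (O2', backbone) are "off-edge"; unknown residue types are retained
    as "unclassified".
    """
    # group event-side atoms by (frame, pair, residue)
    keys: list[tuple] = []
    cands: dict[tuple, list[set[str]]] = {}
    sides: list[tuple[tuple, int]] = []  # (group key, index within group)
    for ev in events:
        pair = ev.pair
        for rid, resname, atom, role in (
                (ev.donor_residue, ev.donor_resname, ev.donor_atom, "donor"),
                (ev.acceptor_residue, ev.acceptor_resname, ev.acceptor_atom,
                 "acceptor")):
            key = (ev.frame, pair, rid)
            known = chem.normalize_resname(resname) in chem.RING_ATOMS
            group = cands.setdefault(key, [])
            group.append(_possible_edges(resname, atom, role)
                         if known else {"unclassified"})
            sides.append((key, len(group) - 1))
            keys.append(key)

    labels: dict[tuple, list[str]] = {}
    for key, group in cands.items():
        if any("unclassified" in c for c in group):
            labels[key] = ["unclassified" if "unclassified" in c else
                           lab for c, lab in zip(group, _pick_edge(
                               [c - {"unclassified"} for c in group]))]
        else:
            labels[key] = _pick_edge(group)

    out: list[ClassifiedHBond] = []
    for i, ev in enumerate(events):
        dkey, dpos = sides[2 * i]
        akey, apos = sides[2 * i + 1]
        out.append(ClassifiedHBond(ev, labels[dkey][dpos], labels[akey][apos]))
    return out


def edge_pair_counts(classified: Sequence[ClassifiedHBond]):
    """Tidy per-frame counts per (residue pair, edge pair).

    Returns a DataFrame with one row per (frame, residue pair, donor edge,
    acceptor edge) and the number of bonds observed.
    """
    import pandas as pd

    rows = []
    for cb in classified:
        ev = cb.event
        rows.append({
            "frame": ev.frame,
            "donor_chain": ev.donor_residue[0],
            "donor_res": ev.donor_residue[1],
            "donor_edge": cb.donor_edge,
            "acceptor_chain": ev.acceptor_residue[0],
            "acceptor_res": ev.acceptor_residue[1],
            "acceptor_edge": cb.acceptor_edge,
        })
    if not rows:
        return pd.DataFrame(columns=[
            "frame", "donor_chain", "donor_res", "donor_edge",
            "acceptor_chain", "acceptor_res", "acceptor_edge", "n_bonds"])
    df = pd.DataFrame(rows)
    return (df.groupby(list(df.columns), as_index=False)
              .size().rename(columns={"size": "n_bonds"}))


# -- distances -------------------------------------------------------------

def _mass_weighted_com(res: ResidueView, atom_names: Iterable[str],
                       parent: AtomicStructure) -> np.ndarray:
    names = list(atom_names)
    missing = [n for n in names if not res.has_atom(n)]
    if missing:
        raise GeometryError(
            f"residue {res.chain_id}:{res.number} ({res.name}) is missing "
            f"atoms {missing}")
    xyz = np.array([res.coord(n) for n in names])
    masses = np.array([
        chem.ATOMIC_MASS[parent.atoms[res.atom_index(n)].element.upper()]
        for n in names])
    return (xyz * masses[:, None]).sum(axis=0) / masses.sum()


def edge_com(frame: AtomicStructure, rid: ResidueId, edge: str) -> np.ndarray:
    """Mass-weighted center of the donor+acceptor heavy atoms of an edge."""
    res = frame.residue(*rid)
    atoms = chem.edge_atoms(res.name, edge)
    return _mass_weighted_com(res, atoms.keys(), frame)


def edge_distance(frame: AtomicStructure, res_a: ResidueId, edge_a: str,
                  res_b: ResidueId, edge_b: str) -> float:
    """Distance between the mass centers of two base-pair edges (Å)."""
    return float(np.linalg.norm(edge_com(frame, res_a, edge_a)
                                - edge_com(frame, res_b, edge_b)))


def guanidinium_edge_distance(frame: AtomicStructure, arg_res: ResidueId,
                              partner_res: ResidueId,
                              partner_edge: str = "WC") -> GuanidiniumDistance:
    """Minimum-edge distance from an arginine guanidinium group to a base edge.

    Computes the centers of mass of the {NE, NH1} and {NE, NH2} donor pairs
    and returns the smaller of the two distances to the partner-edge center;
    ties resolve to the NE,NH1 branch.
    """
    res = frame.residue(*arg_res)
    target = edge_com(frame, partner_res, partner_edge)
    d1 = float(np.linalg.norm(
        _mass_weighted_com(res, ("NE", "NH1"), frame) - target))
    d2 = float(np.linalg.norm(
        _mass_weighted_com(res, ("NE", "NH2"), frame) - target))
    if d2 < d1:
        return GuanidiniumDistance(d2, "NE,NH2")
    return GuanidiniumDistance(d1, "NE,NH1")


def stacking_distance(frame: AtomicStructure, res_a: ResidueId,
                      res_b: ResidueId) -> float:
    """Distance between ring-atom mass centers of two stacking partners (Å).

    For nucleotides the ring is the 6- or 9-membered base ring (exocyclic
    atoms excluded); for arginine the planar guanidinium group
    {CZ, NE, NH1, NH2} stands in as the ring.
    """
    coms = []
    for rid in (res_a, res_b):
        res = frame.residue(*rid)
        name = chem.normalize_resname(res.name)
        ring = chem.RING_ATOMS.get(name)
        if ring is None:
            raise GeometryError(f"no ring defined for residue type {res.name}")
        coms.append(_mass_weighted_com(res, ring, frame))
    return float(np.linalg.norm(coms[0] - coms[1]))


# -- RMSD ------------------------------------------------------------------

def _backbone_indices(s: AtomicStructure,
                      residues: Iterable[ResidueId] | None) -> list[int]:
    ids = list(residues) if residues is not None else list(s.residue_index)
    idx: list[int] = []
    for rid in ids:
        res = s.residue(*rid)
        for name in chem.backbone_atom_names(res.name):
            if res.has_atom(name):
                idx.append(res.atom_index(name))
    return idx


def superposed_rmsd(moving: np.ndarray, reference: np.ndarray) -> float:
    """Least-squares (Kabsch) RMSD between two matched point sets."""
    ref = reference - reference.mean(axis=0)
    mov = moving - moving.mean(axis=0)
    _, rssd = Rotation.align_vectors(ref, mov)
    return float(rssd / np.sqrt(len(ref)))


def backbone_rmsd(traj: Trajectory, reference: AtomicStructure,
                  residues: Iterable[ResidueId] | None = None,
                  superpose: bool = True) -> MetricSeries:
    """Per-frame backbone RMSD to a reference after optimal superposition.

    Backbone means N/CA/C/O for amino acids and P/O5'/C5'/C4'/C3'/O3' for
    nucleotides.  Rigid-body motion is removed frame by frame unless
    ``superpose=False`` (raw coordinate RMSD).
    """
    ids = list(residues) if residues is not None else None
    idx_t = _backbone_indices(traj.topology, ids)
    idx_r = _backbone_indices(reference, ids)
    if len(idx_t) != len(idx_r) or not idx_t:
        raise GeometryError(
            f"backbone selections differ: {len(idx_t)} trajectory atoms vs "
            f"{len(idx_r)} reference atoms")
    ref = reference.coords[idx_r]
    if superpose:
        vals = np.array([superposed_rmsd(traj.frames[f][idx_t], ref)
                         for f in range(traj.n_frames)])
    else:
        vals = np.array([
            float(np.sqrt(np.mean(np.sum(
                (traj.frames[f][idx_t] - ref) ** 2, axis=1))))
            for f in range(traj.n_frames)])
    return MetricSeries("backbone_rmsd", "all" if ids is None else str(ids),
                        vals, traj.frames_per_ns)


# -- time courses ----------------------------------------------------------

def _pair_hbond_count(frame: AtomicStructure, spec: PairSpec,
                      dist_cutoff_A: float, angle_cutoff_deg: float,
                      frame_index: int) -> int:
    donors = (enumerate_donors(frame, [spec.res_a], spec.edge_a)
              + enumerate_donors(frame, [spec.res_b], spec.edge_b))
    acceptors = (enumerate_acceptors(frame, [spec.res_a], spec.edge_a)
                 + enumerate_acceptors(frame, [spec.res_b], spec.edge_b))
    if all(len(d.hydrogens) == 0 for d in donors) and donors:
        raise MissingHydrogenError(
            f"pair {spec.pair_id}: donors carry no hydrogens")
    events = detect_hbonds(frame, donors, acceptors, dist_cutoff_A,
                           angle_cutoff_deg, frame_index)
    n = 0
    for ev in events:
        pair = {ev.donor_residue, ev.acceptor_residue}
        if pair == {spec.res_a, spec.res_b}:
            n += 1
    return n


def _pair_distance(frame: AtomicStructure, spec: PairSpec) -> float:
    name_a = chem.normalize_resname(frame.residue(*spec.res_a).name)
    name_b = chem.normalize_resname(frame.residue(*spec.res_b).name)
    if name_a == "ARG":
        return guanidinium_edge_distance(
            frame, spec.res_a, spec.res_b, spec.edge_b or "WC").distance_A
    if name_b == "ARG":
        return guanidinium_edge_distance(
            frame, spec.res_b, spec.res_a, spec.edge_a or "WC").distance_A
    return edge_distance(frame, spec.res_a, spec.edge_a or "WC",
                         spec.res_b, spec.edge_b or "WC")


def series_extract(traj: Trajectory, pair_specs: Sequence[PairSpec],
                   stride: int = 1,
                   dist_cutoff_A: float = DEFAULT_DIST_CUTOFF_A,
                   angle_cutoff_deg: float = DEFAULT_ANGLE_CUTOFF_DEG,
                   ) -> list[MetricSeries]:
    """Per-frame H-bond counts and/or edge distances for residue pairs.

    ``stride`` subsamples frames; the output series carry
    ``frames_per_ns / stride`` so time axes remain in ns.
    """
    if not pair_specs:
        raise ValueError("no pair specs given")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frame_ids = range(0, traj.n_frames, stride)
    out: list[MetricSeries] = []
    eff_rate = traj.frames_per_ns / stride
    values: dict[tuple[str, str], list[float]] = {
        (spec.pair_id, m): [] for spec in pair_specs for m in spec.metrics}
    for fi in frame_ids:
        frame = traj.frame(fi)
        for spec in pair_specs:
            if "hbond_count" in spec.metrics:
                values[(spec.pair_id, "hbond_count")].append(
                    _pair_hbond_count(frame, spec, dist_cutoff_A,
                                      angle_cutoff_deg, fi))
            if "distance" in spec.metrics:
                values[(spec.pair_id, "distance")].append(
                    _pair_distance(frame, spec))
    for spec in pair_specs:
        for m in spec.metrics:
            out.append(MetricSeries(m, spec.pair_id,
                                    np.asarray(values[(spec.pair_id, m)]),
                                    eff_rate))
    return out


def bin_series(series: MetricSeries, bin_ns: float = 1.0) -> BinnedSeries:
    """Pool a per-frame series into consecutive non-overlapping time bins.

    Each bin's value is the mean over its member frames; a trailing partial
    bin is kept and flagged.  The bin-size-weighted mean of the bin means
    reproduces the overall series mean exactly.
    """
    if not bin_ns > 0:
        raise ValueError("bin_ns must be positive")
    per_bin = max(1, int(round(bin_ns * series.frames_per_ns)))
    n = len(series.values)
    means, counts = [], []
    for start in range(0, n, per_bin):
        chunk = series.values[start:start + per_bin]
        means.append(float(np.mean(chunk)))
        counts.append(len(chunk))
    partial = bool(counts and counts[-1] < per_bin)
    return BinnedSeries(series.metric, series.pair_id, np.asarray(means),
                        np.asarray(counts), bin_ns, partial)
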