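"""Idealized residue geometries and rigid-body helpers.

Templates come from the chemical component dictionary bundled with biotite
(idealized coordinates, explicit hydrogens).  Every template can be brought
into a canonical *base frame*: mass-weighted ring center at the origin, base
plane in z = 0, x axis pointing from the ring center toward the Watson–Crick
edge (for arginine, toward NE of the guanidinium plane).  Generators compose
fixtures by rigid moves of residues expressed in this frame.
"""

from __future__ import annotations

import numpy as np

from . import chemistry as chem
from .structure import Atom, AtomicStructure

__all__ = [
    "ideal_residue",
    "oriented_residue",
    "base_frame_transform",
    "ring_com",
    "plane_normal",
    "kabsch",
    "apply_rigid",
    "rot_z",
    "rot_x",
]

# atoms dropped from templates: free-5'-phosphate extras and the terminal
# carboxyl OXT of the isolated amino acid
_DROP = {"OP3", "HOP3", "HOP2", "OXT", "HXT"}

_EDGE_FOR_FRAME = {"A": "WC", "C": "WC", "G": "WC", "U": "WC"}


def ideal_residue(resname: str, chain_id: str = "X",
                  number: int = 1) -> AtomicStructure:
    """Idealized residue (explicit hydrogens) as a one-residue structure."""
    import biotite.structure.info as info

    arr = info.residue(chem.normalize_resname(resname))
    if arr is None:
        raise KeyError(f"no idealized template for residue {resname!r}")
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        if name in _DROP:
            continue
        atoms.append(Atom(chain_id, number, chem.normalize_resname(resname),
                          name, str(arr.element[i]).capitalize()))
        coords.append(np.asarray(arr.coord[i], dtype=float))
    return AtomicStructure(atoms, np.asarray(coords))


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through a point set (SVD)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[-1]
    return n / np.linalg.norm(n)


def ring_com(s: AtomicStructure, chain_id: str, number: int) -> np.ndarray:
    """Mass-weighted center of a residue's ring atoms."""
    res = s.residue(chain_id, number)
    ring = chem.RING_ATOMS[chem.normalize_resname(res.name)]
    xyz = np.array([res.coord(n) for n in ring])
    masses = np.array([chem.ATOMIC_MASS[
        s.atoms[res.atom_index(n)].element.upper()] for n in ring])
    return (xyz * masses[:, None]).sum(axis=0) / masses.sum()


def rot_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_x(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def apply_rigid(s: AtomicStructure, rotation: np.ndarray,
                translation: np.ndarray) -> AtomicStructure:
    return s.with_coords(s.coords @ rotation.T + translation)


def base_frame_transform(s: AtomicStructure, chain_id: str,
                         number: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation bringing a residue into its canonical base frame.

    Returns ``(R, t)`` such that ``x @ R.T + t`` puts the ring mass center at
    the origin, the ring plane in z = 0 and the x axis toward the edge
    reference atom set.
    """
    res = s.residue(chain_id, number)
    name = chem.normalize_resname(res.name)
    ring = chem.RING_ATOMS[name]
    ring_xyz = np.array([res.coord(n) for n in ring])
    origin = ring_com(s, chain_id, number)
    z = plane_normal(ring_xyz)
    if name == "ARG":
        edge_pt = res.coord("NE")
    else:
        edge = chem.edge_atoms(name, _EDGE_FOR_FRAME[name])
        edge_pt = np.mean([res.coord(a) for a in edge], axis=0)
    x = edge_pt - origin
    x = x - np.dot(x, z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    rot = np.stack([x, y, z])  # rows: new axes in old coordinates
    return rot, -rot @ origin


def oriented_residue(resname: str, chain_id: str = "X",
                     number: int = 1) -> AtomicStructure:
    """Idealized residue expressed in its canonical base frame."""
    s = ideal_residue(resname, chain_id, number)
    rot, t = base_frame_transform(s, chain_id, number)
    return apply_rigid(s, rot, t)


def kabsch(moving: np.ndarray,
           target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform ``(R, t)`` mapping moving → target."""
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    h = (moving - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, ct - rot @ cm
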