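"""Atom-name tables for base-pair edges, H-bond chemistry, rings and backbones.

Edge atom sets follow the Leontis–Westhof taxonomy: each nucleobase presents
a Watson–Crick face and (for purines) a Hoogsteen face, each a small set of
donor/acceptor heavy atoms.  The arginine guanidinium group is treated as an
extra "edge" with three proton-donor nitrogens (NE, NH1, NH2) — it both
stacks and hydrogen-bonds like a base, which is what makes the CAR surface
work.  Hydrogen names follow PDB v3 conventions (H41/H42 on cytosine N4,
HH11/HH12 on arginine NH1, ...).
"""

from __future__ import annotations

__all__ = [
    "ATOMIC_MASS",
    "DONOR_HYDROGENS",
    "ACCEPTORS",
    "WC_EDGE",
    "HOOGSTEEN_EDGE",
    "GUANIDINIUM_EDGE",
    "GUANIDINIUM_DONORS",
    "RING_ATOMS",
    "BACKBONE_ATOMS",
    "NUCLEOTIDES",
    "PURINES",
    "PYRIMIDINES",
    "normalize_resname",
    "edge_atoms",
    "is_nucleotide",
]

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06,
}

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})
NUCLEOTIDES = PURINES | PYRIMIDINES

# residue-name aliases occasionally seen in RNA PDB files
_RESNAME_ALIASES = {
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
    "A5": "A", "C5": "C", "G5": "G", "U5": "U",
    "A3": "A", "C3": "C", "G3": "G", "U3": "U",
}


def normalize_resname(name: str) -> str:
    return _RESNAME_ALIASES.get(name.strip().upper(), name.strip().upper())


def is_nucleotide(resname: str) -> bool:
    return normalize_resname(resname) in NUCLEOTIDES


# Donor heavy atom -> attached hydrogen names, per residue type.  Sugar 2'-OH
# and chain-terminal hydroxyls are included so off-edge bonding (e.g. via
# O2') is detectable, not just the base faces.
DONOR_HYDROGENS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N6": ("H61", "H62"), "O2'": ("HO2'",), "O3'": ("HO3'",),
          "O5'": ("HO5'",)},
    "C": {"N4": ("H41", "H42"), "O2'": ("HO2'",), "O3'": ("HO3'",),
          "O5'": ("HO5'",)},
    "G": {"N1": ("H1",), "N2": ("H21", "H22"), "O2'": ("HO2'",),
          "O3'": ("HO3'",), "O5'": ("HO5'",)},
    "U": {"N3": ("H3",), "O2'": ("HO2'",), "O3'": ("HO3'",),
          "O5'": ("HO5'",)},
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22"),
            "N": ("H", "H2")},
}

# Acceptor heavy atoms per residue type (base + sugar/phosphate oxygens).
_SUGAR_PHOSPHATE_ACCEPTORS = ("OP1", "OP2", "OP3", "O2'", "O3'", "O4'", "O5'")
ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N1", "N3", "N7") + _SUGAR_PHOSPHATE_ACCEPTORS,
    "C": ("N3", "O2") + _SUGAR_PHOSPHATE_ACCEPTORS,
    "G": ("O6", "N3", "N7") + _SUGAR_PHOSPHATE_ACCEPTORS,
    "U": ("O2", "O4") + _SUGAR_PHOSPHATE_ACCEPTORS,
    "ARG": ("O", "OXT"),
}

# Edge atom sets: atom -> "donor" | "acceptor".
WC_EDGE: dict[str, dict[str, str]] = {
    "A": {"N6": "donor", "N1": "acceptor"},
    "C": {"N4": "donor", "N3": "acceptor", "O2": "acceptor"},
    "G": {"O6": "acceptor", "N1": "donor", "N2": "donor"},
    "U": {"N3": "donor", "O2": "acceptor", "O4": "acceptor"},
}

HOOGSTEEN_EDGE: dict[str, dict[str, str]] = {
    "A": {"N6": "donor", "N7": "acceptor"},
    "G": {"O6": "acceptor", "N7": "acceptor"},
}

# The guanidinium "edge" of arginine: three donor nitrogens (plus the
# backbone amide donor N, counted separately in the donor table).
GUANIDINIUM_EDGE: dict[str, str] = {
    "NE": "donor", "NH1": "donor", "NH2": "donor",
}
GUANIDINIUM_DONORS = ("NE", "NH1", "NH2")
GUANIDINIUM_GROUP = ("CZ", "NE", "NH1", "NH2")

# Ring heavy atoms for stacking centers of mass.  Exocyclic atoms excluded;
# the planar guanidinium group stands in as arginine's "ring".
_PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": _PURINE_RING,
    "G": _PURINE_RING,
    "C": _PYRIMIDINE_RING,
    "U": _PYRIMIDINE_RING,
    "ARG": GUANIDINIUM_GROUP,
}

BACKBONE_ATOMS = {
    "protein": ("N", "CA", "C", "O"),
    "nucleic": ("P", "O5'", "C5'", "C4'", "C3'", "O3'"),
}


def backbone_atom_names(resname: str) -> tuple[str, ...]:
    if is_nucleotide(resname):
        return BACKBONE_ATOMS["nucleic"]
    return BACKBONE_ATOMS["protein"]


def edge_atoms(resname: str, edge: str) -> dict[str, str]:
    """Atom -> donor/acceptor map for a residue's named edge.

    ``edge`` is ``"WC"``, ``"Hoogsteen"`` or ``"guanidinium"``.
    """
    name = normalize_resname(resname)
    if edge == "guanidinium":
        if name != "ARG":
            raise KeyError(f"guanidinium edge undefined for {resname}")
        return dict(GUANIDINIUM_EDGE)
    table = {"WC": WC_EDGE, "Hoogsteen": HOOGSTEEN_EDGE}.get(edge)
    if table is None:
        raise KeyError(f"unknown edge {edge!r}")
    if name not in table:
        raise KeyError(f"{edge} edge undefined for residue type {resname!r}")
    return dict(table[name])
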