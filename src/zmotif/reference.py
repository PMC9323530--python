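"""Reference nucleobase geometry and per-base atom tables.

The base templates are idealised planar heavy-atom coordinates in a common
in-plane reference frame (x, y in angstroms, z = 0), with the glycosidic
C1' included.  In this frame the Watson-Crick partner of a base is obtained
by the 180 degree rotation about x (y -> -y, z -> -z), which is how the
fixture module assembles ideal pairs and duplexes.

Atom names use the ASCII apostrophe internally ("O4'"); the unicode prime
found in literature strings ("O4′") is normalised on input and emitted
on output by the annotation modules.
"""

from __future__ import annotations

import numpy as np

PRIME = "′"

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})
STANDARD_BASES = ("A", "C", "G", "U")

#: DNA residue names mapped to the equivalent base type (lp...pi geometry is
#: identical; DNA residues are excluded from RNA motif searches by default).
DNA_EQUIVALENT = {"DA": "A", "DC": "C", "DG": "G", "DT": "U"}


def normalize_atom_name(name: str) -> str:
    """Map unicode primes and PDB v2 asterisks to the ASCII apostrophe."""
    return name.replace(PRIME, "'").replace("*", "'")


def prettify_atom_name(name: str) -> str:
    """Render an internal atom name with the unicode prime for display."""
    return name.replace("'", PRIME)


# Planar base heavy-atom templates (x, y) in the common reference frame.
BASE_TEMPLATES: dict[str, dict[str, np.ndarray]] = {
    "A": {
        "C1'": (-2.479, 5.346),
        "N9": (-1.291, 4.498),
        "C8": (0.024, 4.897),
        "N7": (0.877, 3.902),
        "C5": (0.071, 2.771),
        "C6": (0.369, 1.398),
        "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532),
        "C2": (-1.912, 1.023),
        "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124),
    },
    "G": {
        "C1'": (-2.477, 5.399),
        "N9": (-1.289, 4.551),
        "C8": (0.023, 4.962),
        "N7": (0.870, 3.969),
        "C5": (0.071, 2.833),
        "C6": (0.424, 1.460),
        "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641),
        "C2": (-1.999, 1.087),
        "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364),
        "C4": (-1.265, 3.177),
    },
    "C": {
        "C1'": (-2.477, 5.402),
        "N1": (-1.285, 4.542),
        "C2": (-1.472, 3.158),
        "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344),
        "C4": (0.837, 2.868),
        "N4": (1.875, 2.027),
        "C5": (1.056, 4.275),
        "C6": (-0.023, 5.068),
    },
    "U": {
        "C1'": (-2.481, 5.354),
        "N1": (-1.284, 4.500),
        "C2": (-1.462, 3.131),
        "O2": (-2.563, 2.608),
        "N3": (-0.302, 2.397),
        "C4": (0.989, 2.884),
        "O4": (1.935, 2.094),
        "C5": (1.089, 4.311),
        "C6": (-0.024, 5.053),
    },
}
BASE_TEMPLATES = {
    base: {name: np.array([x, y, 0.0]) for name, (x, y) in atoms.items()}
    for base, atoms in BASE_TEMPLATES.items()
}

#: Glycosidic nitrogen per base type.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

#: Atom defining chi together with O4'-C1'-N: C4 for purines, C2 for pyrimidines.
CHI_REFERENCE = {"A": "C4", "G": "C4", "C": "C2", "U": "C2"}

#: Ring-atom cycles, in bonded order (used for polygons and ellipse fits).
RING_ATOMS: dict[str, list[list[str]]] = {
    # purines: 6-ring first, then 5-ring
    "A": [["C4", "C5", "C6", "N1", "C2", "N3"], ["N9", "C8", "N7", "C5", "C4"]],
    "G": [["C4", "C5", "C6", "N1", "C2", "N3"], ["N9", "C8", "N7", "C5", "C4"]],
    "C": [["N1", "C2", "N3", "C4", "C5", "C6"]],
    "U": [["N1", "C2", "N3", "C4", "C5", "C6"]],
}

#: Full set of ring atoms per base (annotation prerequisite).
ALL_RING_ATOMS = {
    base: sorted({a for ring in rings for a in ring})
    for base, rings in RING_ATOMS.items()
}

#: Exocyclic heavy atoms included in the base geometric center.
EXOCYCLIC_ATOMS = {"A": ["N6"], "G": ["O6", "N2"], "C": ["O2", "N4"], "U": ["O2", "O4"]}

#: Vectors whose cross product fixes the sign of the base normal so that the
#: positive normal points toward the 3'-face: (origin, p, q) with
#: normal ~ (p - origin) x (q - origin).  Calibrated once against an ideal
#: A-form helix: the normal of residue i must point toward residue i+1.
NORMAL_CONVENTION = {
    "A": ("N9", "C8", "C4"),
    "G": ("N9", "C8", "C4"),
    "C": ("N1", "C6", "C2"),
    "U": ("N1", "C6", "C2"),
}

#: Backbone oxygen atoms that can act as lone-pair...pi donors.
BACKBONE_OXYGENS = ("OP1", "OP2", "O2'", "O3'", "O4'", "O5'")

# ---------------------------------------------------------------------------
# Leontis-Westhof edge membership and hydrogen-bonding tables
# ---------------------------------------------------------------------------

#: Base-edge membership for Watson-Crick (W), Hoogsteen/C-H (H) and Sugar (S)
#: edges.  The ribose 2'-OH belongs to the sugar edge of every nucleotide.
EDGE_ATOMS: dict[str, dict[str, frozenset]] = {
    "A": {
        "W": frozenset({"N1", "C2", "N6"}),
        "H": frozenset({"N6", "N7", "C8"}),
        "S": frozenset({"N3", "C2", "O2'"}),
    },
    "G": {
        "W": frozenset({"N1", "N2", "O6"}),
        "H": frozenset({"O6", "N7", "C8"}),
        "S": frozenset({"N3", "N2", "O2'"}),
    },
    "C": {
        "W": frozenset({"N3", "N4", "O2"}),
        "H": frozenset({"N4", "C5", "C6"}),
        "S": frozenset({"O2", "O2'"}),
    },
    "U": {
        "W": frozenset({"N3", "O4", "O2"}),
        "H": frozenset({"O4", "C5", "C6"}),
        "S": frozenset({"O2", "O2'"}),
    },
}

#: Hydrogen-bond donor heavy atoms with their covalent antecedent (for the
#: antecedent-donor-acceptor angle test).  O2' can donate on any nucleotide.
HBOND_DONORS: dict[str, dict[str, str]] = {
    "A": {"N6": "C6", "O2'": "C2'"},
    "G": {"N1": "C6", "N2": "C2", "O2'": "C2'"},
    "C": {"N4": "C4", "O2'": "C2'"},
    "U": {"N3": "C2", "O2'": "C2'"},
}

#: Hydrogen-bond acceptor heavy atoms.
HBOND_ACCEPTORS: dict[str, tuple] = {
    "A": ("N1", "N3", "N7", "O2'"),
    "G": ("N3", "N7", "O6", "O2'"),
    "C": ("N3", "O2", "O2'"),
    "U": ("O2", "O4", "O2'"),
}


def base_heavy_atoms(base: str, include_exocyclic: bool = True) -> list[str]:
    """Heavy-atom names entering the base geometric center."""
    names = list(ALL_RING_ATOMS[base])
    if include_exocyclic:
        names += EXOCYCLIC_ATOMS[base]
    return names
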