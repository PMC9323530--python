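"""Core record types: one RNA residue with named atoms, and structure metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .reference import ALL_RING_ATOMS, BACKBONE_OXYGENS, STANDARD_BASES


class NtKey(NamedTuple):
    """Identity of a nucleotide: model, chain, author residue number, insertion code."""

    model: int
    chain: str
    seq_number: int
    insertion_code: str = ""

    def label(self, base_type: str = "") -> str:
        icode = self.insertion_code or ""
        return f"{base_type}{self.seq_number}{icode}:{self.chain}"


@dataclass
class NucleotideRecord:
    """One RNA residue: named heavy-atom coordinates plus occupancy/altloc maps.

    Coordinates are in angstroms.  Atom names use the ASCII apostrophe
    ("O4'").  ``is_dna`` marks DA/DC/DG/DT residues, which are parsed but
    excluded from RNA motif searches unless explicitly requested.
    """

    structure_id: str
    model: int
    chain: str
    seq_number: int
    insertion_code: str
    base_type: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    occupancy: dict[str, float] = field(default_factory=dict)
    altloc: dict[str, str] = field(default_factory=dict)
    is_dna: bool = False

    def __post_init__(self) -> None:
        if self.base_type not in STANDARD_BASES:
            raise ValueError(f"unsupported base type {self.base_type!r}")

    @property
    def key(self) -> NtKey:
        return NtKey(self.model, self.chain, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return self.key.label(self.base_type)

    @property
    def is_purine(self) -> bool:
        return self.base_type in ("A", "G")

    def has_atoms(self, names) -> bool:
        return all(n in self.atoms for n in names)

    @property
    def annotatable(self) -> bool:
        """All base-ring atoms plus C1' present."""
        return self.has_atoms(ALL_RING_ATOMS[self.base_type]) and "C1'" in self.atoms

    def backbone_oxygens(self) -> list[str]:
        return [n for n in BACKBONE_OXYGENS if n in self.atoms]

    def coords(self, names) -> np.ndarray:
        return np.array([self.atoms[n] for n in names])


@dataclass
class StructureMeta:
    """Structure-level metadata used for survey filtering."""

    structure_id: str
    resolution: float | None = None
    method: str = ""
    n_models: int = 1

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            self.resolution = None
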