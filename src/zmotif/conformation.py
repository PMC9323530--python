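"""Glycosidic conformation, sugar pucker, and ribose mutual orientation.

chi is the torsion O4'-C1'-N9-C4 (purines) or O4'-C1'-N1-C2 (pyrimidines).
The syn window is [0, 90] degrees and the anti window [150, 180] union
(-180, -90]; everything else is reported as intermediate.  The windows are
configurable because borderline chi values are common in Z-step 3'
nucleotides, where a stacking-face constraint is the more robust filter.

Sugar pucker uses the standard pseudorotation analysis of the five
endocyclic torsions nu0..nu4 (nu2 = C1'-C2'-C3'-C4' at phase zero):

    tan(P) = (nu4 + nu1 - nu3 - nu0) / (2 nu2 (sin 36 + sin 72))
    nu_max = nu2 / cos(P)

with class bands C3'-endo P in [0, 36), C4'-exo [36, 72), C2'-endo
[144, 180), otherwise "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import dihedral, unit
from .records import NucleotideRecord
from .reference import CHI_REFERENCE, GLYCOSIDIC_N

RIBOSE_RING = ("C1'", "C2'", "C3'", "C4'", "O4'")

#: torsion atom quadruples for nu0..nu4 (Altona-Sundaralingam numbering)
NU_TORSIONS = (
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
)

_SIN36_SIN72 = np.sin(np.radians(36.0)) + np.sin(np.radians(72.0))


@dataclass
class GlycosidicAnnotation:
    chi: float  # degrees in (-180, 180]
    cls: str  # syn | anti | intermediate


@dataclass
class PuckerAnnotation:
    phase_P: float  # degrees in [0, 360)
    amplitude: float  # degrees
    cls: str  # C3'-endo | C4'-exo | C2'-endo | other
    degenerate: bool = False


@dataclass
class ChiWindows:
    """syn/anti classification windows (degrees)."""

    syn: tuple = (0.0, 90.0)
    anti_low: float = 150.0  # anti: [anti_low, 180] U (-180, anti_high]
    anti_high: float = -90.0

    def classify(self, chi: float) -> str:
        if self.syn[0] <= chi <= self.syn[1]:
            return "syn"
        if chi >= self.anti_low or chi <= self.anti_high:
            return "anti"
        return "intermediate"


def glycosidic(nt: NucleotideRecord, windows: ChiWindows | None = None) -> GlycosidicAnnotation:
    """chi torsion and syn/anti class of one nucleotide."""
    windows = windows or ChiWindows()
    n_gly = GLYCOSIDIC_N[nt.base_type]
    c_ref = CHI_REFERENCE[nt.base_type]
    needed = ("O4'", "C1'", n_gly, c_ref)
    if not nt.has_atoms(needed):
        raise ValueError(f"{nt.label}: missing atoms for chi")
    chi = dihedral(*(nt.atoms[a] for a in needed))
    return GlycosidicAnnotation(chi=chi, cls=windows.classify(chi))


def pucker_from_torsions(nus) -> tuple[float, float]:
    """(phase P in [0, 360), amplitude) from the five endocyclic torsions."""
    nu0, nu1, nu2, nu3, nu4 = nus
    y = (nu4 + nu1) - (nu3 + nu0)
    x = 2.0 * nu2 * _SIN36_SIN72
    P = float(np.degrees(np.arctan2(y, x))) % 360.0
    amplitude = float(np.hypot(x / (2.0 * _SIN36_SIN72), y / (2.0 * _SIN36_SIN72)))
    return P, amplitude


def classify_pucker_phase(P: float) -> str:
    if 0.0 <= P < 36.0:
        return "C3'-endo"
    if 36.0 <= P < 72.0:
        return "C4'-exo"
    if 144.0 <= P < 180.0:
        return "C2'-endo"
    return "other"


def pucker(nt: NucleotideRecord) -> PuckerAnnotation:
    """Pseudorotation phase/amplitude and pucker class of the ribose ring."""
    if not nt.has_atoms(RIBOSE_RING):
        raise ValueError(f"{nt.label}: incomplete ribose ring")
    nus = [dihedral(*(nt.atoms[a] for a in quad)) for quad in NU_TORSIONS]
    if all(abs(v) < 1e-9 for v in nus):
        return PuckerAnnotation(phase_P=0.0, amplitude=0.0, cls="other", degenerate=True)
    P, amp = pucker_from_torsions(nus)
    return PuckerAnnotation(phase_P=P, amplitude=amp, cls=classify_pucker_phase(P))


def ribose_orientation(nt1: NucleotideRecord, nt2: NucleotideRecord) -> str:
    """Advisory head-to-head / head-to-tail ribose orientation heuristic.

    In a regular helix successive riboses point the same way (head-to-tail);
    in a Z-step they face each other (head-to-head).  The heuristic compares
    the O4'->C1' direction vectors: head_to_head requires a negative dot
    product and each O4' on the facing side of the other ribose's mean
    plane; a positive dot product is head_to_tail; anything else is
    undetermined.  Advisory only - never used as a hard motif filter.
    """
    for nt in (nt1, nt2):
        if not nt.has_atoms(RIBOSE_RING):
            return "undetermined"
    v1 = unit(nt1.atoms["C1'"] - nt1.atoms["O4'"])
    v2 = unit(nt2.atoms["C1'"] - nt2.atoms["O4'"])
    dot = float(np.dot(v1, v2))
    if dot > 0.0:
        return "head_to_tail"
    c1 = nt1.coords(RIBOSE_RING).mean(axis=0)
    c2 = nt2.coords(RIBOSE_RING).mean(axis=0)
    n1 = _ring_plane_normal(nt1)
    n2 = _ring_plane_normal(nt2)
    # orient each normal toward the other ribose
    if np.dot(n1, c2 - c1) < 0:
        n1 = -n1
    if np.dot(n2, c1 - c2) < 0:
        n2 = -n2
    facing1 = np.dot(nt2.atoms["O4'"] - c1, n1) > 0
    facing2 = np.dot(nt1.atoms["O4'"] - c2, n2) > 0
    if facing1 and facing2:
        return "head_to_head"
    return "undetermined"


def _ring_plane_normal(nt: NucleotideRecord) -> np.ndarray:
    xyz = nt.coords(RIBOSE_RING)
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]
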