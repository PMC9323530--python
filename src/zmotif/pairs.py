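"""Hydrogen-bond detection, Leontis-Westhof pair classification, and
base-base stacking faces.

This is a deliberately reduced classifier: the families required by the
Z-motif queries (cWW, tSW/tWS and their "near" variants) are the supported
surface; other edge combinations are reported best-effort and flagged
``provisional``.  Edges are assigned per base by majority vote over the
edge membership of the hydrogen-bonded atoms (the ribose 2'-OH counts as
sugar edge); cis/trans comes from the side of the C1'-C1' axis on which
the two glycosidic bonds fall, measured in the mean pair plane.

Stacking uses the base frames: two bases stack when each base's center
projects inside the other's expanded-ellipse ring system with a signed
normal offset of 2.0-4.5 A; the face letters (s33/s35/s53/s55) read the
engaged face of nt1 then nt2 (s53 = nt1's 5'-face against nt2's 3'-face).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base_frames import BaseFrame, FrameError, compute_base_frame, locate_projection
from .geometry import angle
from .records import NucleotideRecord, NtKey
from .reference import EDGE_ATOMS, GLYCOSIDIC_N, HBOND_ACCEPTORS, HBOND_DONORS


@dataclass
class HBond:
    donor_nt: NtKey
    donor_atom: str
    acceptor_nt: NtKey
    acceptor_atom: str
    distance: float
    angle: float  # antecedent-donor-acceptor, degrees

    @property
    def near(self) -> bool:
        return self.distance > 3.5


@dataclass
class PairAnnotation:
    nt1: NtKey
    nt2: NtKey
    family: str  # e.g. cWW, tSW, tWS
    edges: tuple  # (edge1, edge2) in {W, H, S}
    orientation: str  # cis | trans
    near: bool
    hbonds: list = field(default_factory=list)
    provisional: bool = False

    @property
    def rendered(self) -> str:
        return ("n" if self.near else "") + self.family


@dataclass
class StackAnnotation:
    nt1: NtKey
    nt2: NtKey
    faces: str  # s33 | s35 | s53 | s55
    near: bool
    z_offset: float


@dataclass
class PairParameters:
    """Geometric thresholds for hydrogen bonds, pairing and stacking."""

    hbond_max: float = 3.5  # A, heavy-atom donor-acceptor
    hbond_near_max: float = 4.0
    hbond_min_angle: float = 110.0  # antecedent-donor-acceptor, degrees
    coplanarity_max: float = 35.0  # inter-plane angle for true pairs
    coplanarity_near_max: float = 55.0
    stack_z_min: float = 2.0
    stack_z_max: float = 4.5


def detect_hbonds(nt1: NucleotideRecord, nt2: NucleotideRecord,
                  params: PairParameters | None = None) -> list[HBond]:
    """Geometric hydrogen bonds between two nucleotides (both directions).

    Donor and acceptor heavy atoms come from per-base tables; a bond needs
    donor-acceptor distance <= ``hbond_near_max`` (<= ``hbond_max`` for a
    non-near bond) and an antecedent-donor-acceptor angle >= 110 degrees.
    """
    params = params or PairParameters()
    out = []
    for a, b in ((nt1, nt2), (nt2, nt1)):
        donors = HBOND_DONORS[a.base_type]
        acceptors = HBOND_ACCEPTORS[b.base_type]
        for d_atom, antecedent in donors.items():
            if d_atom not in a.atoms or antecedent not in a.atoms:
                continue
            for acc in acceptors:
                if acc not in b.atoms:
                    continue
                dist = float(np.linalg.norm(a.atoms[d_atom] - b.atoms[acc]))
                if dist > params.hbond_near_max or dist < 2.2:
                    continue
                ang = angle(a.atoms[antecedent], a.atoms[d_atom], b.atoms[acc])
                if ang < params.hbond_min_angle:
                    continue
                out.append(HBond(a.key, d_atom, b.key, acc, dist, ang))
    out.sort(key=lambda h: h.distance)
    return out


def _edge_votes(nt: NucleotideRecord, atoms) -> dict:
    votes = {"W": 0, "H": 0, "S": 0}
    tables = EDGE_ATOMS[nt.base_type]
    for atom in atoms:
        for edge, members in tables.items():
            if atom in members:
                votes[edge] += 1
    return votes


def _majority_edge(votes: dict):
    ranked = sorted(votes.items(), key=lambda kv: -kv[1])
    if ranked[0][1] == 0 or ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def classify_lw(nt1: NucleotideRecord, nt2: NucleotideRecord,
                params: PairParameters | None = None,
                frames: dict | None = None) -> PairAnnotation | None:
    """Classify a base pair into a Leontis-Westhof family, or return None.

    Requires at least one detected hydrogen bond, an unambiguous edge per
    base, and approximate coplanarity.  ``near`` pairs are those held only
    by long (3.5-4.0 A) hydrogen bonds or with borderline coplanarity
    (35-55 degrees).  Families other than cWW/tSW/tWS carry
    ``provisional=True``.
    """
    params = params or PairParameters()
    try:
        f1 = _get_frame(nt1, frames)
        f2 = _get_frame(nt2, frames)
    except FrameError:
        return None
    hbonds = detect_hbonds(nt1, nt2, params)
    if not hbonds:
        return None

    plane_angle = float(np.degrees(np.arccos(np.clip(
        abs(np.dot(f1.normal, f2.normal)), -1.0, 1.0))))
    if plane_angle > params.coplanarity_near_max:
        return None
    near = plane_angle > params.coplanarity_max
    true_bonds = [h for h in hbonds if not h.near]
    if not true_bonds:
        near = True

    # edges are voted by the firmly bonded atoms; long (near) bonds only
    # count when nothing better holds the pair together
    voting = true_bonds or hbonds
    atoms1 = [h.donor_atom if h.donor_nt == nt1.key else h.acceptor_atom for h in voting]
    atoms2 = [h.donor_atom if h.donor_nt == nt2.key else h.acceptor_atom for h in voting]
    e1 = _majority_edge(_edge_votes(nt1, atoms1))
    e2 = _majority_edge(_edge_votes(nt2, atoms2))
    if e1 is None or e2 is None:
        return None

    orientation = _cis_trans(nt1, nt2, f1, f2)
    family = orientation[0] + e1 + e2
    provisional = family not in ("cWW", "tSW", "tWS")
    return PairAnnotation(
        nt1=nt1.key, nt2=nt2.key, family=family, edges=(e1, e2),
        orientation=orientation, near=near, hbonds=hbonds,
        provisional=provisional,
    )


def _get_frame(nt: NucleotideRecord, frames: dict | None) -> BaseFrame:
    if frames is not None:
        if nt.key not in frames:
            frames[nt.key] = compute_base_frame(nt)
        return frames[nt.key]
    return compute_base_frame(nt)


def _cis_trans(nt1, nt2, f1: BaseFrame, f2: BaseFrame) -> str:
    """cis when the two glycosidic bonds fall on the same side of the
    C1'-C1' axis in the mean pair plane, trans otherwise."""
    c1a = nt1.atoms["C1'"]
    c1b = nt2.atoms["C1'"]
    axis = c1b - c1a
    mean_normal = f1.normal + (f2.normal if np.dot(f1.normal, f2.normal) > 0
                               else -f2.normal)
    mean_normal /= np.linalg.norm(mean_normal)
    axis = axis - np.dot(axis, mean_normal) * mean_normal
    n_axis = np.cross(mean_normal, axis)
    g1 = nt1.atoms[GLYCOSIDIC_N[nt1.base_type]] - c1a
    g2 = nt2.atoms[GLYCOSIDIC_N[nt2.base_type]] - c1b
    s1 = np.dot(g1, n_axis)
    s2 = np.dot(g2, n_axis)
    return "cis" if s1 * s2 > 0 else "trans"


def classify_stack(nt1: NucleotideRecord, nt2: NucleotideRecord,
                   params: PairParameters | None = None,
                   frames: dict | None = None) -> StackAnnotation | None:
    """Face-on-face base stacking: s33, s35, s53 or s55, or None.

    True stack: each base's center projects inside the other's expanded
    ellipse system with 2.0 < |z| <= 4.5 A, in both directions.  When only
    one direction satisfies the test, the stack is reported ``near``.
    """
    params = params or PairParameters()
    try:
        f1 = _get_frame(nt1, frames)
        f2 = _get_frame(nt2, frames)
    except FrameError:
        return None

    def one_way(fa: BaseFrame, other_center):
        x, y, z = fa.project(other_center)
        ok_z = params.stack_z_min < abs(z) <= params.stack_z_max
        loc = locate_projection(fa, (x, y))
        return ok_z and loc.kind != "outside", z

    ok12, z2_in_1 = one_way(f1, f2.center)  # where nt2 sits relative to nt1
    ok21, z1_in_2 = one_way(f2, f1.center)
    if not (ok12 or ok21):
        return None
    near = not (ok12 and ok21)
    # engaged face of nt1 = side of nt1 where nt2's center lies, and vice versa
    face1 = 3 if z2_in_1 > 0 else 5
    face2 = 3 if z1_in_2 > 0 else 5
    return StackAnnotation(
        nt1=nt1.key, nt2=nt2.key, faces=f"s{face1}{face2}", near=near,
        z_offset=float(abs(z2_in_1)),
    )
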