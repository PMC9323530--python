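"""Lone-pair...pi (oxygen...pi) contact annotation.

A contact is the stacking of a backbone oxygen (OP1, OP2, O2', O3', O4',
O5') over a nucleobase face.  With z the signed coordinate of the oxygen
along the base normal (z > 0 on the 3'-face):

* true contact:  2.0 < |z| <= 3.5 A and the in-plane projection falls
  strictly inside a base-ring polygon;
* near, case 1:  3.5 < |z| <= 3.6 A, projection inside a ring;
* near, case 2:  |z| <= 3.5 A, projection outside every ring polygon but
  inside an ellipse expanded 0.3 A beyond the ring corners.

The 2.0 A lower bound excludes rare "in-plane" contacts and is applied to
all three cases.  Per ordered (base, oxygen-owner) nucleotide pair at most
one oxygen is annotated: among true candidates the smallest |z| wins, then
among case-1 candidates the smallest |z|, then among case-2 candidates the
projection closest to the base center.

Contacts are rendered as directional strings: sO4'3 (the O4' atom of the
oxygen-owner stacks on the 3'-face of the base) and the mirror s3O4' (the
base's 3'-face stacks with the O4' of the partner).  A leading "n" marks a
near contact.  Output strings use the unicode prime.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .base_frames import BaseFrame, FrameError, compute_base_frame, locate_projection
from .records import NucleotideRecord, NtKey
from .reference import BACKBONE_OXYGENS, normalize_atom_name, prettify_atom_name


@dataclass
class LpPiParameters:
    """Cutoffs of the contact definition (angstroms)."""

    z_max_true: float = 3.5
    z_max_near: float = 3.6
    z_min: float = 2.0
    ellipse_expansion: float = 0.3
    oxygen_atoms: tuple = BACKBONE_OXYGENS
    #: apply the z_min in-plane exclusion to the near cases as well
    z_min_applies_to_near: bool = True
    #: annotate a residue's own backbone oxygens over its own base (diagnostics)
    include_intra: bool = False
    #: candidate pruning radius; non-lossy since |z| <= z_max_near and the
    #: in-plane extent of the expanded ring system is < 3 A
    prune_radius: float = 7.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.z_min < self.z_max_true < self.z_max_near):
            raise ValueError("require 0 <= z_min < z_max_true < z_max_near")


@dataclass
class LpPiAnnotation:
    """One oxygen...face contact between two nucleotides."""

    structure_id: str
    base_nt: NtKey
    oxygen_nt: NtKey
    oxygen_atom: str  # internal name, ASCII apostrophe
    face: int  # 3 or 5
    z: float  # signed, A
    xy: tuple
    category: str  # "true" | "near"
    ring_id: int = 0

    @property
    def oxygen_first_string(self) -> str:
        pre = "ns" if self.category == "near" else "s"
        return f"{pre}{prettify_atom_name(self.oxygen_atom)}{self.face}"

    @property
    def base_first_string(self) -> str:
        pre = "ns" if self.category == "near" else "s"
        return f"{pre}{self.face}{prettify_atom_name(self.oxygen_atom)}"

    def row(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "base_model": self.base_nt.model,
            "base_chain": self.base_nt.chain,
            "base_seq": self.base_nt.seq_number,
            "base_icode": self.base_nt.insertion_code,
            "oxy_model": self.oxygen_nt.model,
            "oxy_chain": self.oxygen_nt.chain,
            "oxy_seq": self.oxygen_nt.seq_number,
            "oxy_icode": self.oxygen_nt.insertion_code,
            "oxygen_atom": prettify_atom_name(self.oxygen_atom),
            "face": self.face,
            "z": round(self.z, 3),
            "category": self.category,
            "oxygen_first": self.oxygen_first_string,
            "base_first": self.base_first_string,
        }


def annotate_pair(
    base_nt: NucleotideRecord,
    frame: BaseFrame,
    oxygen_nt: NucleotideRecord,
    params: LpPiParameters | None = None,
) -> LpPiAnnotation | None:
    """Annotate at most one oxygen...pi contact for an ordered nucleotide pair.

    ``base_nt`` supplies the base face (with its precomputed ``frame``);
    ``oxygen_nt`` supplies the backbone oxygens.  Returns ``None`` when no
    oxygen meets any of the three cases.
    """
    params = params or LpPiParameters()
    if base_nt.key == oxygen_nt.key and not params.include_intra:
        return None

    true_cands = []  # (|z|, name, z, xy, ring)
    near1_cands = []
    near2_cands = []  # (dist-to-center, name, z, xy, ring)
    for name in params.oxygen_atoms:
        if name not in oxygen_nt.atoms:
            continue
        x, y, z = frame.project(oxygen_nt.atoms[name])
        az = abs(z)
        if az > params.z_max_near:
            continue
        loc = locate_projection(frame, (x, y))
        if loc.kind == "inside_ring":
            if az <= params.z_min:
                continue  # in-plane exclusion
            ring = _closest_ring(frame, (x, y), loc.ring_ids)
            if az <= params.z_max_true:
                true_cands.append((az, name, z, (x, y), ring))
            else:
                near1_cands.append((az, name, z, (x, y), ring))
        elif loc.kind == "inside_expanded_ellipse" and az <= params.z_max_true:
            if params.z_min_applies_to_near and az <= params.z_min:
                continue
            ring = _closest_ring(frame, (x, y), loc.ring_ids)
            d_center = float(np.hypot(x, y))
            near2_cands.append((d_center, name, z, (x, y), ring))

    if true_cands:
        _, name, z, xy, ring = min(true_cands)
        category = "true"
    elif near1_cands:
        _, name, z, xy, ring = min(near1_cands)
        category = "near"
    elif near2_cands:
        _, name, z, xy, ring = min(near2_cands)
        category = "near"
    else:
        return None
    return LpPiAnnotation(
        structure_id=base_nt.structure_id,
        base_nt=base_nt.key,
        oxygen_nt=oxygen_nt.key,
        oxygen_atom=name,
        face=3 if z > 0 else 5,
        z=z,
        xy=xy,
        category=category,
        ring_id=ring,
    )


def _closest_ring(frame: BaseFrame, xy, ring_ids) -> int:
    """Tie-break dual-ring membership by the nearer ring-polygon centroid."""
    if len(ring_ids) == 1:
        return ring_ids[0]
    xy = np.asarray(xy)
    return min(
        ring_ids,
        key=lambda i: float(np.linalg.norm(frame.ring_polygons[i].mean(axis=0) - xy)),
    )


def scan_structure(
    records,
    params: LpPiParameters | None = None,
    near: bool = True,
    frames: dict | None = None,
):
    """Annotate all oxygen...pi contacts among a list of nucleotide records.

    Every ordered (base, oxygen-owner) pair whose base center lies within
    ``params.prune_radius`` of an oxygen atom is examined.  Output order is
    deterministic: (base key, oxygen-owner key).  ``near=False`` restricts
    the output to true contacts.  Precomputed ``frames`` (key -> BaseFrame)
    may be passed to avoid recomputation.
    """
    params = params or LpPiParameters()
    records = [r for r in records if r.annotatable]
    if frames is None:
        frames = {}
        for rec in records:
            try:
                frames[rec.key] = compute_base_frame(
                    rec, ellipse_expansion=params.ellipse_expansion
                )
            except FrameError:
                continue

    keys = [r.key for r in records]
    by_key = {r.key: r for r in records}
    centers = np.array([frames[k].center for k in keys if k in frames])
    framed_keys = [k for k in keys if k in frames]

    # representative point per oxygen owner for pruning
    annos = []
    for bi, bkey in enumerate(framed_keys):
        base_rec = by_key[bkey]
        frame = frames[bkey]
        for okey in keys:
            if okey == bkey and not params.include_intra:
                continue
            oxy_rec = by_key[okey]
            if oxy_rec.model != base_rec.model:
                continue
            near_enough = any(
                np.linalg.norm(oxy_rec.atoms[a] - frame.center) <= params.prune_radius
                for a in params.oxygen_atoms
                if a in oxy_rec.atoms
            )
            if not near_enough:
                continue
            anno = annotate_pair(base_rec, frame, oxy_rec, params)
            if anno is not None and (near or anno.category == "true"):
                annos.append(anno)
    annos.sort(key=lambda a: (a.base_nt, a.oxygen_nt))
    return annos


# ---------------------------------------------------------------------------
# Constraint strings
# ---------------------------------------------------------------------------

_OXYGEN_TOKENS = ("OP1", "OP2", "O2'", "O3'", "O4'", "O5'", "OP", "O")

_CONSTRAINT_RE = re.compile(
    r"^(?P<near>n\+|n)?s(?P<face1>[35])?(?P<oxy>OP1|OP2|O2'|O3'|O4'|O5'|OP|O)(?P<face2>[35])?$"
)


class ConstraintError(ValueError):
    """Malformed lp...pi constraint string."""


@dataclass
class LpPiConstraint:
    """Parsed form of a directional lp...pi constraint string.

    ``base_first`` is True for the s3O4' form (first nucleotide of the
    edge owns the base face) and False for the sO4'3 / sO form (first
    nucleotide owns the oxygen).
    """

    near_mode: str  # "true" | "near" | "both"
    face: int | None  # 3, 5 or None (either face)
    oxygen: str  # internal name, or "O"/"OP" generics
    base_first: bool
    text: str = ""

    def matches(self, anno: LpPiAnnotation) -> bool:
        if self.near_mode == "true" and anno.category != "true":
            return False
        if self.near_mode == "near" and anno.category != "near":
            return False
        if self.face is not None and anno.face != self.face:
            return False
        if self.oxygen == "O":
            return anno.oxygen_atom in BACKBONE_OXYGENS
        if self.oxygen == "OP":
            return anno.oxygen_atom in ("OP1", "OP2")
        return anno.oxygen_atom == self.oxygen


def parse_constraint(text: str) -> LpPiConstraint:
    """Parse a constraint such as sO, sOP, s3O4', sO4'3, nsO4'3 or n+sO4'3.

    Both the unicode prime and the ASCII apostrophe are accepted.  A face
    digit before the oxygen token (s3O4') puts the base first; after it
    (sO4'3), the oxygen first; no digit means either face (oxygen-first
    direction, e.g. plain sO).
    """
    cleaned = normalize_atom_name(text.strip())
    m = _CONSTRAINT_RE.match(cleaned)
    if not m:
        pos = _first_bad_position(cleaned)
        raise ConstraintError(f"malformed lp...pi constraint {text!r} (at position {pos})")
    if m.group("face1") and m.group("face2"):
        raise ConstraintError(
            f"constraint {text!r} names a face on both sides "
            f"(at position {m.start('face2')})"
        )
    near = m.group("near")
    near_mode = {"n": "near", "n+": "both", None: "true"}[near]
    face = m.group("face1") or m.group("face2")
    return LpPiConstraint(
        near_mode=near_mode,
        face=int(face) if face else None,
        oxygen=m.group("oxy"),
        base_first=bool(m.group("face1")),
        text=text.strip(),
    )


def _first_bad_position(cleaned: str) -> int:
    probe = cleaned
    while probe:
        if _CONSTRAINT_RE.match(probe):
            return len(cleaned) - len(probe)
        probe = probe[:-1]
    return 0


def match_constraint(annotation: LpPiAnnotation, constraint: str) -> bool:
    """Whether a contact annotation satisfies a textual constraint.

    The annotation describes one directed contact (base side and oxygen
    side are fixed); direction handling across a motif edge is the query
    engine's job, via ``LpPiConstraint.base_first``.
    """
    return parse_constraint(constraint).matches(annotation)
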