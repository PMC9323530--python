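"""Nucleobase reference frames: center, signed normal, in-plane system, ring ellipses.

The convention throughout the package is that the positive side of the base
normal is the 3'-face: the face that points toward the 3'-direction in a
regular RNA helix.  The sign is fixed per base type from the cross product
of two intra-base vectors (see ``reference.NORMAL_CONVENTION``), calibrated
once against an ideal A-form helix, and is therefore invariant under any
rigid-body motion of the structure.

Each base ring also carries two closed curves used by the contact
annotator: the polygon through the ring atoms (the strict "inside a ring"
test) and an ellipse fitted to the ring atoms and expanded so its boundary
passes 0.3 A radially beyond the most outlying ring corner (the "near"
boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import unit
from .records import NucleotideRecord
from .reference import (
    CHI_REFERENCE,
    GLYCOSIDIC_N,
    NORMAL_CONVENTION,
    RING_ATOMS,
    base_heavy_atoms,
)


class FrameError(ValueError):
    """Raised when a base frame cannot be computed (missing ring atoms)."""


@dataclass
class RingEllipse:
    """In-plane ellipse associated with one base ring.

    ``expansion`` = 0 for the fitted ellipse; the expanded copy stores the
    radial margin (0.3 A by default) and the already-scaled semi-axes.
    """

    ring_atoms: tuple
    center_2d: np.ndarray
    semi_axes: tuple  # (a, b), a >= b
    orientation: float  # radians, direction of the major axis
    expansion: float = 0.0
    residual: float = 0.0

    def contains(self, xy) -> bool:
        x, y = np.asarray(xy, dtype=float) - self.center_2d
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = c * x + s * y
        v = -s * x + c * y
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def scaled(self, factor: float, expansion: float) -> "RingEllipse":
        return RingEllipse(
            self.ring_atoms,
            self.center_2d.copy(),
            (self.semi_axes[0] * factor, self.semi_axes[1] * factor),
            self.orientation,
            expansion=expansion,
            residual=self.residual,
        )


@dataclass
class BaseFrame:
    """Geometric frame of one nucleobase."""

    center: np.ndarray
    normal: np.ndarray  # unit vector toward the 3'-face
    basis: tuple  # two orthonormal in-plane vectors (b1, b2)
    ring_polygons: list  # per ring: (n, 2) in-plane ring-atom coordinates
    rings: list  # fitted RingEllipse per ring
    expanded_rings: list  # expanded RingEllipse per ring
    base_type: str = ""

    def project(self, point):
        """Return (x, y, z): in-plane coordinates and signed normal coordinate.

        z > 0 means the point lies on the 3'-face side of the base plane.
        """
        d = np.asarray(point, dtype=float) - self.center
        return (
            float(np.dot(d, self.basis[0])),
            float(np.dot(d, self.basis[1])),
            float(np.dot(d, self.normal)),
        )

    def unproject(self, x, y, z):
        return self.center + x * self.basis[0] + y * self.basis[1] + z * self.normal


@dataclass
class ProjectionLocation:
    """Classification of an in-plane point against the ring system."""

    kind: str  # inside_ring | inside_expanded_ellipse | outside
    ring_ids: tuple = ()


def compute_base_frame(nt: NucleotideRecord, include_exocyclic: bool = True,
                       ellipse_expansion: float = 0.3) -> BaseFrame:
    """Compute the base frame of a nucleotide.

    The plane is the total-least-squares plane through the ring atoms
    (smallest singular vector of the centred coordinates); the center is
    the unweighted mean of the base heavy atoms (exocyclic O/N included by
    default, toggleable for sensitivity analysis).
    """
    base = nt.base_type
    ring_names = [a for ring in RING_ATOMS[base] for a in ring]
    ring_names = list(dict.fromkeys(ring_names))
    missing = [a for a in ring_names if a not in nt.atoms]
    if missing:
        raise FrameError(f"{nt.label}: missing ring atoms {missing}")

    center_names = [a for a in base_heavy_atoms(base, include_exocyclic) if a in nt.atoms]
    center = nt.coords(center_names).mean(axis=0)

    ring_xyz = nt.coords(ring_names)
    centered = ring_xyz - ring_xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]

    o, p, q = NORMAL_CONVENTION[base]
    conv = np.cross(nt.atoms[p] - nt.atoms[o], nt.atoms[q] - nt.atoms[o])
    if np.dot(normal, conv) < 0:
        normal = -normal
    normal = unit(normal)

    # deterministic in-plane basis: b1 along the glycosidic-N -> chi-reference
    # bond projected into the plane
    ref = nt.atoms[CHI_REFERENCE[base]] - nt.atoms[GLYCOSIDIC_N[base]]
    b1 = unit(ref - np.dot(ref, normal) * normal)
    b2 = np.cross(normal, b1)

    frame = BaseFrame(center=center, normal=normal, basis=(b1, b2),
                      ring_polygons=[], rings=[], expanded_rings=[], base_type=base)

    for ring in RING_ATOMS[base]:
        pts2d = np.array([frame.project(nt.atoms[a])[:2] for a in ring])
        frame.ring_polygons.append(pts2d)
        ell = fit_ring_ellipse(pts2d, ring_atoms=tuple(ring))
        frame.rings.append(ell)
        frame.expanded_rings.append(_expand_ellipse(ell, pts2d, ellipse_expansion))
    return frame


def fit_ring_ellipse(points_2d, ring_atoms: tuple = ()) -> RingEllipse:
    """Least-squares conic fit of 5 or 6 in-plane points, constrained to an ellipse.

    Uses the numerically stable direct ellipse-specific fit of Halir &
    Flusser.  The reported residual is the RMS radial distance of the
    points to the fitted boundary.
    """
    pts = np.asarray(points_2d, dtype=float)
    if pts.shape[0] < 5:
        raise ValueError("ellipse fit needs at least 5 points")
    mean = pts.mean(axis=0)
    x, y = (pts - mean).T
    spread = np.linalg.matrix_rank(np.c_[x, y], tol=1e-8)
    if spread < 2:
        raise ValueError("degenerate (collinear) ring points")

    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    C = np.array([[0.0, 0.0, 2.0], [0.0, -1.0, 0.0], [2.0, 0.0, 0.0]])
    M = np.linalg.solve(C, M)
    w, v = np.linalg.eig(M)
    cond = 4.0 * v[0] * v[2] - v[1] ** 2
    idx = np.flatnonzero(np.real(cond) > 0)
    if idx.size == 0:
        raise ValueError("no ellipse solution for these points")
    a1 = np.real(v[:, idx[0]])
    coeffs = np.concatenate([a1, T @ a1])  # A, B, C, D, E, F about the mean

    A, B, Cc, D, E, F = coeffs
    # conic -> geometric parameters
    M0 = np.array([[A, B / 2], [B / 2, Cc]])
    rhs = np.array([-D / 2, -E / 2])
    c_local = np.linalg.solve(M0, rhs)
    Fc = F + D / 2 * c_local[0] + E / 2 * c_local[1]
    evals, evecs = np.linalg.eigh(M0)
    if -Fc / evals[0] <= 0 or -Fc / evals[1] <= 0:
        raise ValueError("conic is not a real ellipse")
    axes = np.sqrt(-Fc / evals)  # eigh: ascending evals -> descending axes
    a, b = float(axes[0]), float(axes[1])
    major = evecs[:, 0]
    if a < b:  # keep a >= b
        a, b = b, a
        major = evecs[:, 1]
    orientation = float(np.arctan2(major[1], major[0]))

    ell = RingEllipse(ring_atoms, c_local + mean, (a, b), orientation)
    ell.residual = _rms_radial_residual(ell, pts)
    return ell


def _boundary_radius(ell: RingEllipse, theta: float) -> float:
    """Distance from the ellipse center to its boundary along direction theta."""
    c, s = np.cos(ell.orientation), np.sin(ell.orientation)
    u = c * np.cos(theta) + s * np.sin(theta)
    v = -s * np.cos(theta) + c * np.sin(theta)
    a, b = ell.semi_axes
    return 1.0 / np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _rms_radial_residual(ell: RingEllipse, pts) -> float:
    d = pts - ell.center_2d
    r = np.linalg.norm(d, axis=1)
    th = np.arctan2(d[:, 1], d[:, 0])
    rb = np.array([_boundary_radius(ell, t) for t in th])
    return float(np.sqrt(np.mean((r - rb) ** 2)))


def _expand_ellipse(ell: RingEllipse, pts2d, margin: float) -> RingEllipse:
    """Scale the fitted ellipse about its center so that its boundary passes
    ``margin`` A radially beyond the most outlying ring atom."""
    d = pts2d - ell.center_2d
    r = np.linalg.norm(d, axis=1)
    i = int(np.argmax(r))
    theta = np.arctan2(d[i, 1], d[i, 0])
    factor = (r[i] + margin) / _boundary_radius(ell, theta)
    return ell.scaled(factor, margin)


def _point_in_polygon(xy, poly) -> bool:
    """Strict even-odd point-in-polygon (boundary counts as outside)."""
    x, y = xy
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xin:
                inside = not inside
    return inside


def locate_projection(frame: BaseFrame, xy) -> ProjectionLocation:
    """Classify an in-plane point against the ring polygons and expanded ellipses.

    ``inside_ring``: strictly inside at least one ring-atom polygon.
    ``inside_expanded_ellipse``: outside every polygon but inside at least
    one expanded ellipse.  Dual-ring membership for purines is reported as
    a tuple of ring ids; tie-breaking is the annotator's concern.
    """
    xy = np.asarray(xy, dtype=float)
    in_rings = tuple(
        i for i, poly in enumerate(frame.ring_polygons) if _point_in_polygon(xy, poly)
    )
    if in_rings:
        return ProjectionLocation("inside_ring", in_rings)
    in_ells = tuple(i for i, e in enumerate(frame.expanded_rings) if e.contains(xy))
    if in_ells:
        return ProjectionLocation("inside_expanded_ellipse", in_ells)
    return ProjectionLocation("outside")
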