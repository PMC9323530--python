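"""Independent brute-force oracles used by the test suite.

Everything here is written against the *definitions* (least-squares plane,
point-in-polygon, conic inequality, explicit case enumeration for the
contact rules) using shapely and plain numpy, independently of the package
implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, Polygon

from zmotif.reference import (
    EXOCYCLIC_ATOMS,
    NORMAL_CONVENTION,
    RING_ATOMS,
)


def frame_oracle(rec, include_exocyclic=True):
    """(center, normal, ring polygons in 3D) from first principles."""
    base = rec.base_type
    ring_names = list(dict.fromkeys(a for ring in RING_ATOMS[base] for a in ring))
    names = ring_names + ([a for a in EXOCYCLIC_ATOMS[base] if a in rec.atoms]
                          if include_exocyclic else [])
    center = np.mean([rec.atoms[a] for a in names], axis=0)
    ring_xyz = np.array([rec.atoms[a] for a in ring_names])
    u, s, vt = np.linalg.svd(ring_xyz - ring_xyz.mean(axis=0))
    normal = vt[2]
    o, p, q = NORMAL_CONVENTION[base]
    conv = np.cross(rec.atoms[p] - rec.atoms[o], rec.atoms[q] - rec.atoms[o])
    if np.dot(normal, conv) < 0:
        normal = -normal
    return center, normal / np.linalg.norm(normal)


def project_oracle(center, normal, basis, point):
    d = np.asarray(point) - center
    return np.dot(d, basis[0]), np.dot(d, basis[1]), np.dot(d, normal)


def shapely_ring_polygons(frame):
    return [Polygon(poly) for poly in frame.ring_polygons]


def ellipse_inequality(ellipse, xy) -> bool:
    """Conic inequality membership test for a RingEllipse."""
    x, y = np.asarray(xy) - ellipse.center_2d
    c, s = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    u = c * x + s * y
    v = -s * x + c * y
    a, b = ellipse.semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def locate_oracle(frame, xy):
    """Brute-force projection classification via shapely + conic inequality."""
    pt = Point(*xy)
    in_rings = [i for i, poly in enumerate(shapely_ring_polygons(frame))
                if poly.contains(pt)]
    if in_rings:
        return "inside_ring", tuple(in_rings)
    in_ells = [i for i, e in enumerate(frame.expanded_rings)
               if ellipse_inequality(e, xy)]
    if in_ells:
        return "inside_expanded_ellipse", tuple(in_ells)
    return "outside", ()


def lppi_oracle(frame, oxygen_positions, params):
    """Enumerate every (oxygen, ring, case) combination explicitly.

    ``oxygen_positions``: dict atom name -> 3D position.  Returns
    (atom, category, face) or None, mirroring the published selection
    rules: smallest |z| inside a ring in the true band, else smallest |z|
    inside a ring in the 3.5-3.6 band, else the expanded-ellipse candidate
    closest to the base center; the >z_min exclusion applies everywhere.
    """
    true_c, near1_c, near2_c = [], [], []
    for name, pos in oxygen_positions.items():
        x, y, z = frame.project(pos)
        az = abs(z)
        kind, ids = locate_oracle(frame, (x, y))
        if kind == "inside_ring":
            if az <= params.z_min:
                continue
            if az <= params.z_max_true:
                true_c.append((az, name, z))
            elif az <= params.z_max_near:
                near1_c.append((az, name, z))
        elif kind == "inside_expanded_ellipse" and az <= params.z_max_true:
            if params.z_min_applies_to_near and az <= params.z_min:
                continue
            near2_c.append((float(np.hypot(x, y)), name, z))
    for cands, cat in ((true_c, "true"), (near1_c, "near"), (near2_c, "near")):
        if cands:
            _, name, z = min(cands)
            return name, cat, (3 if z > 0 else 5)
    return None


def plane_fit_residual(points, normal, center):
    """RMS distance of points to the plane (center, normal)."""
    return float(np.sqrt(np.mean(((points - center) @ normal) ** 2)))


def best_three_point_plane_residual(points):
    """Minimum RMS distance over all planes through 3 of the points.

    The total-least-squares plane minimises the RMS distance over every
    plane, so it must beat all of these.
    """
    from itertools import combinations

    best = np.inf
    for i, j, k in combinations(range(len(points)), 3):
        n = np.cross(points[j] - points[i], points[k] - points[i])
        nn = np.linalg.norm(n)
        if nn < 1e-9:
            continue
        n = n / nn
        d = float(np.sqrt(np.mean(((points - points[i]) @ n) ** 2)))
        best = min(best, d)
    return best
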