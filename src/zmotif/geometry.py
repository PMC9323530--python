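"""Small 3D geometry helpers shared by the annotation and fixture modules.

All coordinates are in angstroms, all angles in degrees unless a function
name says otherwise.  Everything here is plain numpy; no chemistry.
"""

from __future__ import annotations

import numpy as np

Vec3 = np.ndarray


def unit(v: Vec3) -> Vec3:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def angle(a: Vec3, b: Vec3, c: Vec3) -> float:
    """Bond angle a-b-c in degrees."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(p1: Vec3, p2: Vec3, p3: Vec3, p4: Vec3) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_atom(a: Vec3, b: Vec3, c: Vec3, bond: float, ang: float, tors: float) -> Vec3:
    """Place atom D so that |CD|=bond, angle(B,C,D)=ang, torsion(A,B,C,D)=tors.

    The natural-extension (NeRF) construction used by chain builders.
    """
    ang_r = np.radians(ang)
    tors_r = np.radians(tors)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang_r),
            bond * np.sin(ang_r) * np.cos(tors_r),
            -bond * np.sin(ang_r) * np.sin(tors_r),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_from_vector(rv: Vec3) -> np.ndarray:
    """Rotation matrix from a rotation vector (axis * angle in radians)."""
    theta = np.linalg.norm(rv)
    if theta < 1e-12:
        return np.eye(3)
    k = rv / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, Vec3]:
    """Least-squares rigid superposition: returns (R, t) with R@mobile_i + t ~ target_i."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two matched coordinate sets after optimal superposition."""
    R, t = kabsch(a, b)
    moved = a @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
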