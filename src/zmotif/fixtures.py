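"""Synthetic, ground-truth-labelled nucleotide geometries.

Every annotation rule in the package can be exercised offline against
fixtures built here.  Nucleotides are assembled from a single embedded
planar base template per base type plus a ribose generated from the
pseudorotation model: the ring is built so that re-measuring its
pseudorotation phase and amplitude recovers the requested values to
numerical precision, and the base is attached so that the measured chi
torsion equals the requested value exactly.  Fixtures are deterministic:
identical parameters and seed give byte-identical coordinates.

The multi-nucleotide builders (Z-step, Z_anti-step, UNCG Z-turn, A-form
duplex, Z-helix) place rigid nucleotides by small deterministic
optimisations that satisfy the labelled geometry exactly where it is part
of the label (the oxygen position over the base face) and approximately
where it is plumbing (backbone O3'-P adjacency, absence of clashes).
Fixtures are not stereochemically refined models; they exist to exercise
the geometric definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, root

from .base_frames import compute_base_frame
from .conformation import NU_TORSIONS, pucker_from_torsions
from .geometry import dihedral, kabsch, place_atom, rotation_from_vector
from .records import NucleotideRecord
from .reference import BASE_TEMPLATES, CHI_REFERENCE, GLYCOSIDIC_N, NORMAL_CONVENTION

__all__ = [
    "FixtureSpec",
    "build_fixture",
    "build_nucleotide",
    "build_pair",
    "build_zstep",
    "build_zanti_step",
    "build_uncg_zturn",
    "build_aform_duplex",
    "build_zhelix",
    "perturb",
    "write_fixture",
]


class FixtureError(ValueError):
    """Requested fixture geometry is infeasible."""


@dataclass
class FixtureSpec:
    """Declarative description of a fixture: kind, parameters, seed."""

    kind: str  # single_nt | pair | zstep | zanti_step | uncg_zturn | aform_duplex | zhelix
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def build_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to the matching builder and apply seeded noise."""
    builders = {
        "single_nt": lambda **kw: [build_nucleotide(**kw)],
        "pair": build_pair,
        "zstep": build_zstep,
        "zanti_step": build_zanti_step,
        "uncg_zturn": build_uncg_zturn,
        "aform_duplex": build_aform_duplex,
        "zhelix": build_zhelix,
    }
    if spec.kind not in builders:
        raise FixtureError(f"unknown fixture kind {spec.kind!r}")
    params = dict(spec.parameters)
    sigma = params.pop("noise_sigma", 0.0)
    records = builders[spec.kind](**params)
    if sigma > 0.0:
        records = perturb(records, sigma, spec.seed)
    return records


# ---------------------------------------------------------------------------
# single nucleotide
# ---------------------------------------------------------------------------

# ribose internal geometry (bond lengths A, bond angles deg)
_B_C1C2, _B_C2C3, _B_C3C4, _B_C4O4 = 1.526, 1.525, 1.523, 1.451
_A_C1C2C3, _A_C2C3C4, _A_C3C4O4 = 101.5, 102.7, 105.5

# substituent torsion offsets relative to the endocyclic torsions, matching
# beta-D-ribofuranose chirality
_OFF_N, _OFF_O2, _OFF_O3, _OFF_C5 = -125.0, -117.0, 121.0, -121.5


def _ribose_ring(pucker_P: float, amplitude: float) -> dict[str, np.ndarray]:
    """Five-membered ring with exactly the requested pseudorotation state.

    The ring is chain-built from the two driving torsions nu2, nu3 and the
    pair is solved numerically so that the re-measured (P, amplitude)
    equals the request to ~1e-10.
    """

    def build(t2: float, t3: float) -> dict[str, np.ndarray]:
        c1 = np.zeros(3)
        c2 = np.array([_B_C1C2, 0.0, 0.0])
        th = np.radians(180.0 - _A_C1C2C3)
        c3 = c2 + _B_C2C3 * np.array([np.cos(th), np.sin(th), 0.0])
        c4 = place_atom(c1, c2, c3, _B_C3C4, _A_C2C3C4, t2)
        o4 = place_atom(c2, c3, c4, _B_C4O4, _A_C3C4O4, t3)
        return {"C1'": c1, "C2'": c2, "C3'": c3, "C4'": c4, "O4'": o4}

    target = np.array(
        [
            amplitude * np.cos(np.radians(pucker_P)),
            amplitude * np.sin(np.radians(pucker_P)),
        ]
    )
    if amplitude == 0.0:
        return build(0.0, 0.0)

    def residual(t):
        ring = build(t[0], t[1])
        nus = [dihedral(*(ring[a] for a in quad)) for quad in NU_TORSIONS]
        P, amp = pucker_from_torsions(nus)
        got = np.array([amp * np.cos(np.radians(P)), amp * np.sin(np.radians(P))])
        return got - target

    x0 = np.array(
        [
            amplitude * np.cos(np.radians(pucker_P)),
            amplitude * np.cos(np.radians(pucker_P + 144.0)),
        ]
    )
    starts = [x0, 0.8 * x0, 1.2 * x0, x0 + np.array([5.0, -5.0]), x0 + np.array([-5.0, 5.0])]
    for guess in starts:
        sol = root(residual, guess, tol=1e-13)
        if sol.success and np.max(np.abs(residual(sol.x))) < 1e-8:
            return build(*sol.x)
    raise FixtureError(f"cannot realise pucker P={pucker_P}, amplitude={amplitude}")


def set_backbone(nt: NucleotideRecord, gamma: float = 54.0, beta: float = 180.0,
                 alpha: float = -60.0) -> NucleotideRecord:
    """(Re)build O5', P, OP1, OP2 from the given backbone torsions, in place."""
    a = nt.atoms
    a["O5'"] = place_atom(a["C3'"], a["C4'"], a["C5'"], 1.423, 110.5, gamma)
    a["P"] = place_atom(a["C4'"], a["C5'"], a["O5'"], 1.593, 120.9, beta)
    a["OP1"] = place_atom(a["C5'"], a["O5'"], a["P"], 1.485, 108.0, alpha + 115.0)
    a["OP2"] = place_atom(a["C5'"], a["O5'"], a["P"], 1.485, 108.0, alpha - 115.0)
    for name in ("O5'", "P", "OP1", "OP2"):
        nt.occupancy[name] = 1.0
        nt.altloc[name] = ""
    return nt


def build_nucleotide(
    base: str,
    chi: float = -160.0,
    pucker_P: float = 18.0,
    amplitude: float = 40.0,
    gamma: float = 54.0,
    beta: float = 180.0,
    chain: str = "A",
    seq_number: int = 1,
    structure_id: str = "FIXTURE",
    model: int = 1,
) -> NucleotideRecord:
    """Build one complete ribonucleotide with exact chi and sugar pucker.

    ``chi`` is the glycosidic torsion in degrees; ``pucker_P``/``amplitude``
    the pseudorotation state of the ribose.  The base is a rigid planar
    template; re-measuring chi and (P, amplitude) on the result recovers
    the inputs to numerical precision.
    """
    if base not in BASE_TEMPLATES:
        raise FixtureError(f"unknown base {base!r}")
    atoms = _ribose_ring(pucker_P, amplitude)
    nus = [dihedral(*(atoms[a] for a in quad)) for quad in NU_TORSIONS]

    template = BASE_TEMPLATES[base]
    n_name = GLYCOSIDIC_N[base]
    c_ref = CHI_REFERENCE[base]

    # glycosidic nitrogen on the correct ring face, then the chi-defining
    # atom at exactly the requested torsion
    d_c1n = float(np.linalg.norm(template[n_name] - template["C1'"]))
    n_pos = place_atom(atoms["C4'"], atoms["O4'"], atoms["C1'"], d_c1n, 108.5,
                       nus[0] + _OFF_N)
    d_ncr = float(np.linalg.norm(template[c_ref] - template[n_name]))
    v1 = template["C1'"] - template[n_name]
    v2 = template[c_ref] - template[n_name]
    ang_c1ncr = float(
        np.degrees(np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
    )
    cref_pos = place_atom(atoms["O4'"], atoms["C1'"], n_pos, d_ncr, ang_c1ncr, chi)

    # rigid map of the base template onto the three anchors
    src = np.array([template["C1'"], template[n_name], template[c_ref]])
    dst = np.array([atoms["C1'"], n_pos, cref_pos])
    R, t = kabsch(src, dst)
    for name, xyz in template.items():
        if name == "C1'":
            continue
        atoms[name] = R @ xyz + t

    # exocyclic ribose substituents and 5' branch
    atoms["O2'"] = place_atom(atoms["C4'"], atoms["C3'"], atoms["C2'"], 1.413, 112.0,
                              nus[2] + _OFF_O2)
    atoms["O3'"] = place_atom(atoms["C1'"], atoms["C2'"], atoms["C3'"], 1.423, 110.5,
                              nus[2] + _OFF_O3)
    atoms["C5'"] = place_atom(atoms["C2'"], atoms["C3'"], atoms["C4'"], 1.510, 115.5,
                              nus[3] + _OFF_C5)

    nt = NucleotideRecord(
        structure_id=structure_id,
        model=model,
        chain=chain,
        seq_number=seq_number,
        insertion_code="",
        base_type=base,
        atoms=atoms,
        occupancy={k: 1.0 for k in atoms},
        altloc={k: "" for k in atoms},
    )
    return set_backbone(nt, gamma=gamma, beta=beta)


def transform(nt: NucleotideRecord, R: np.ndarray, t: np.ndarray) -> NucleotideRecord:
    """Return a copy of a nucleotide under the rigid motion x -> R x + t."""
    out = NucleotideRecord(
        structure_id=nt.structure_id,
        model=nt.model,
        chain=nt.chain,
        seq_number=nt.seq_number,
        insertion_code=nt.insertion_code,
        base_type=nt.base_type,
        atoms={k: R @ v + t for k, v in nt.atoms.items()},
        occupancy=dict(nt.occupancy),
        altloc=dict(nt.altloc),
        is_dna=nt.is_dna,
    )
    return out


def perturb(records, sigma: float, seed: int = 0):
    """Apply seeded isotropic Gaussian noise (A) to every atom."""
    rng = np.random.default_rng(seed)
    out = []
    for nt in records:
        new = transform(nt, np.eye(3), np.zeros(3))
        for name in sorted(new.atoms):
            new.atoms[name] = new.atoms[name] + rng.normal(0.0, sigma, 3)
        out.append(new)
    return out


def _renumber(records, chain="A", start=1):
    for i, nt in enumerate(records):
        nt.chain = chain
        nt.seq_number = start + i
    return records


# ---------------------------------------------------------------------------
# rigid placement optimisation
# ---------------------------------------------------------------------------

_BASE_ATOM_CACHE: dict = {}


def _base_atom_names(nt: NucleotideRecord):
    return [n for n in BASE_TEMPLATES[nt.base_type] if n != "C1'"]


def _quick_normal(coords: dict, base: str) -> np.ndarray:
    """Cheap convention-signed base normal from three stored atoms."""
    from .reference import NORMAL_CONVENTION

    o, p, q = NORMAL_CONVENTION[base]
    n = np.cross(coords[p] - coords[o], coords[q] - coords[o])
    return n / np.linalg.norm(n)


def _clash(a_coords, b_coords, exempt=(), cutoff=2.5) -> float:
    pen = 0.0
    for na, xa in a_coords.items():
        for nb, xb in b_coords.items():
            if (na, nb) in exempt:
                continue
            d = np.linalg.norm(xa - xb)
            if d < cutoff:
                pen += (cutoff - d) ** 2
    return pen


_ROT_STARTS = [np.zeros(3)] + [
    ang * np.array(ax)
    for ang in (0.9, 1.8, 2.7)
    for ax in ((1, 0, 0), (0, 1, 0), (0, 0, 1), (0.577, 0.577, 0.577))
]


def _optimize_pinned(nt: NucleotideRecord, pin_atom: str, pin_target: np.ndarray,
                     score, extra0=()) -> tuple[NucleotideRecord, np.ndarray, float]:
    """Rotate ``nt`` about its ``pin_atom`` (pinned exactly onto ``pin_target``)
    to minimise ``score(moved_array, extra_params)``; the array rows follow
    ``list(nt.atoms)`` order.  Deterministic starts."""
    p0 = nt.atoms[pin_atom].copy()
    names = list(nt.atoms)
    xyz0 = np.array([nt.atoms[n] - p0 for n in names])
    extra0 = np.asarray(extra0, dtype=float)

    def moved(params):
        R = rotation_from_vector(params[:3])
        return xyz0 @ R.T + pin_target

    def f(params):
        return score(moved(params), params[3:])

    best = None
    for rv in _ROT_STARTS:
        x0 = np.concatenate([rv, extra0])
        res = minimize(f, x0, method="Powell",
                       options={"maxiter": 4000, "xtol": 1e-6, "ftol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    arr = moved(best.x)
    out = transform(nt, np.eye(3), np.zeros(3))
    out.atoms = dict(zip(names, arr))
    return out, best.x[3:], float(best.fun)


def _optimize_free(nt: NucleotideRecord, score, guesses) -> tuple[NucleotideRecord, float]:
    """6-dof rigid placement of ``nt`` minimising ``score(arr)``; ``guesses``
    is a list of (R, t) initial poses tried deterministically.  The array
    rows follow ``list(nt.atoms)`` order."""
    names = list(nt.atoms)
    center = np.mean([nt.atoms[n] for n in names], axis=0)
    xyz0 = np.array([nt.atoms[n] - center for n in names])

    best = None
    for R0, t0 in guesses:
        base_pts = xyz0 @ R0.T

        def moved(params, base_pts=base_pts, t0=t0):
            R = rotation_from_vector(params[:3])
            return base_pts @ R.T + t0 + params[3:]

        def f(params, moved=moved):
            return score(moved(params))

        res = minimize(f, np.zeros(6), method="Powell",
                       options={"maxiter": 5000, "xtol": 1e-6, "ftol": 1e-8})
        if best is None or res.fun < best[1].fun:
            best = (moved, res)
    moved_fn, res = best
    arr = moved_fn(res.x)
    out = transform(nt, np.eye(3), np.zeros(3))
    out.atoms = dict(zip(names, arr))
    return out, float(res.fun)


def _bond_term(d: float, target: float = 1.6, weight: float = 4.0) -> float:
    return weight * (d - target) ** 2


# ---------------------------------------------------------------------------
# Z-step and Z_anti-step
# ---------------------------------------------------------------------------


def _build_step(bases, z, xy_offset, chi1, chi2, pucker1, pucker2, antiparallel):
    """Shared core: nt1's O4' pinned over nt2's principal ring at signed z."""
    nt2 = build_nucleotide(bases[1], chi=chi2, pucker_P=pucker2, seq_number=2)
    frame2 = compute_base_frame(nt2)
    cen = frame2.ring_polygons[0].mean(axis=0)
    xy_offset = np.asarray(xy_offset, dtype=float)
    q = frame2.unproject(cen[0] + xy_offset[0], cen[1] + xy_offset[1], z)

    nt1 = build_nucleotide(bases[0], chi=chi1, pucker_P=pucker1, seq_number=1)
    names1 = list(nt1.atoms)
    i_base1 = [names1.index(n) for n in _base_atom_names(nt1)]
    o_name, p_name, q_name = NORMAL_CONVENTION[bases[0]]
    i_conv = [names1.index(n) for n in (o_name, p_name, q_name)]
    i_oxy = [names1.index(n) for n in ("OP1", "OP2", "O2'", "O3'", "O5'")]
    i_o3 = names1.index("O3'")
    i_o4 = names1.index("O4'")
    i_c1 = names1.index("C1'")
    # far lateral offsets are negative controls; the stacked-bases targets
    # only apply to the genuine step geometry
    stack_w = 1.0 if float(np.hypot(*xy_offset)) <= 1.5 else 0.0
    ring_centroids = [poly.mean(axis=0) for poly in frame2.ring_polygons]
    v2_ribose = nt2.atoms["C1'"] - nt2.atoms["O4'"]
    v2_ribose = v2_ribose / np.linalg.norm(v2_ribose)
    _rib_names = ("C1'", "C2'", "C3'", "C4'", "O4'")
    i_rib = [names1.index(n) for n in _rib_names]
    rib2_pts = np.array([nt2.atoms[n] for n in _rib_names])
    rib2_c = rib2_pts.mean(axis=0)
    rib2_n = np.cross(rib2_pts[1] - rib2_pts[0], rib2_pts[3] - rib2_pts[0])
    rib2_n = rib2_n / np.linalg.norm(rib2_n)
    arr2_o4 = nt2.atoms["O4'"]
    s_norm = -1.0 if antiparallel else 1.0
    z_sign = np.sign(z) if z != 0 else 1.0
    n2 = frame2.normal
    b1v, b2v = frame2.basis
    c2v = frame2.center

    names2 = list(nt2.atoms)
    nt2_work = transform(nt2, np.eye(3), np.zeros(3))
    # clash mask: exempt the pinned O4' against everything (its position is
    # the planted label) and the nascent O3'-phosphate linkage
    exempt_pairs = np.zeros((len(names1), len(names2)), dtype=bool)
    exempt_pairs[i_o4, :] = True
    for n2name in ("P", "O5'", "OP1", "OP2"):
        exempt_pairs[i_o3, names2.index(n2name)] = True

    def score(arr1, extra):
        gamma2, beta2 = extra
        set_backbone(nt2_work, gamma=54.0 + gamma2, beta=180.0 + beta2)
        arr2 = np.array([nt2_work.atoms[n] for n in names2])
        pen = _bond_term(np.linalg.norm(arr1[i_o3] - nt2_work.atoms["P"]), weight=12.0)
        c1 = arr1[i_base1].mean(axis=0)
        o, p, qq = arr1[i_conv]
        n1 = np.cross(p - o, qq - o)
        n1 /= np.linalg.norm(n1)
        d = c1 - c2v
        x, y, zc = np.dot(d, b1v), np.dot(d, b2v), np.dot(d, n2)
        r = min(
            np.hypot(x - rc[0], y - rc[1]) for rc in ring_centroids
        )
        t = z_sign * zc
        pen += stack_w * 0.5 * (max(0.0, 2.6 - t) ** 2 + max(0.0, t - 4.4) ** 2)
        pen += stack_w * 0.6 * (float(np.dot(n1, n2)) - s_norm) ** 2
        zc2 = float(np.dot(c2v - c1, n1))
        pen += stack_w * 0.3 * (max(0.0, 2.6 + zc2) ** 2)
        # head-to-head ribose orientation: O4'->C1' vectors antiparallel and
        # each O4' on the face of the other ribose's mean plane
        v1_rib = arr1[i_c1] - arr1[i_o4]
        hh = float(np.dot(v1_rib, v2_ribose)) / np.linalg.norm(v1_rib)
        pen += stack_w * 5.0 * max(0.0, hh + 0.55) ** 2
        r1c = arr1[i_rib].mean(axis=0)
        rn1 = np.cross(arr1[i_rib[1]] - arr1[i_rib[0]], arr1[i_rib[3]] - arr1[i_rib[0]])
        rn1 /= np.linalg.norm(rn1)
        if np.dot(rn1, rib2_c - r1c) < 0:
            rn1 = -rn1
        face1 = float(np.dot(arr2_o4 - r1c, rn1))
        rn2o = rib2_n if np.dot(rib2_n, r1c - rib2_c) > 0 else -rib2_n
        face2 = float(np.dot(arr1[i_o4] - rib2_c, rn2o))
        pen += stack_w * 3.0 * (max(0.0, 0.8 - face1) ** 2 + max(0.0, 0.8 - face2) ** 2)
        zo = np.abs((arr1[i_oxy] - c2v) @ n2)
        ro = np.hypot((arr1[i_oxy] - c2v) @ b1v, (arr1[i_oxy] - c2v) @ b2v)
        close = zo < 4.2
        pen += float(np.sum(np.maximum(0.0, 3.0 - ro[close]) ** 2))
        dd = np.linalg.norm(arr1[:, None, :] - arr2[None, :, :], axis=2)
        viol = np.maximum(0.0, 2.5 - dd)
        viol[exempt_pairs] = 0.0
        pen += float(np.sum(viol**2))
        return pen

    nt1_placed, extra, fun = _optimize_pinned(nt1, "O4'", q, score, extra0=(0.0, 0.0))
    set_backbone(nt2_work, gamma=54.0 + extra[0], beta=180.0 + extra[1])
    bond = np.linalg.norm(nt1_placed.atoms["O3'"] - nt2_work.atoms["P"])
    # negative-control placements (far lateral offset) are only used for
    # contact tests; covalent closure is best-effort there
    max_bond = 1.9 if stack_w else 2.8
    if bond > max_bond:
        raise FixtureError(
            f"infeasible step geometry: O3'-P closure {bond:.2f} A (z={z}, xy={xy_offset})"
        )
    return _renumber([nt1_placed, nt2_work])


def _construct_stacked_step(bases, z, chi1, chi2, pucker1, pucker2, antiparallel):
    """Closed-form two-base arrangement carrying both the oxygen...pi contact
    and the mutual face-on-face stacking label (s53 / s55).

    The 5' nucleotide is placed rigidly: base plane parallel (antiparallel
    for the s55 variant) to the 3' base, O4' pinned over the 3' base's
    principal ring (shifted 0.6 A off the five-membered ring for purines),
    and the base center swung toward the ring system.  No covalent O3'-P
    linkage is constructed; this fixture labels stacking geometry only.
    """
    nt2 = build_nucleotide(bases[1], chi=chi2, pucker_P=pucker2, seq_number=2)
    frame2 = compute_base_frame(nt2)
    cen = frame2.ring_polygons[0].mean(axis=0)
    off = np.zeros(2)
    if len(frame2.ring_polygons) > 1:
        cen5 = frame2.ring_polygons[1].mean(axis=0)
        u = cen - cen5
        off = 0.6 * u / np.linalg.norm(u)
    q = frame2.unproject(cen[0] + off[0], cen[1] + off[1], z)
    n2 = frame2.normal

    nt1 = build_nucleotide(bases[0], chi=chi1, pucker_P=pucker1, seq_number=1)
    f1 = compute_base_frame(nt1)
    target_n = -n2 if antiparallel else n2
    v_axis = np.cross(f1.normal, target_n)
    s_n, c_n = np.linalg.norm(v_axis), float(np.dot(f1.normal, target_n))
    if s_n < 1e-9:
        R0 = np.eye(3) if c_n > 0 else rotation_from_vector(np.pi * frame2.basis[0])
    else:
        R0 = rotation_from_vector(v_axis / s_n * np.arctan2(s_n, c_n))
    v = R0 @ (nt1.atoms["O4'"] - f1.center)
    v_lat = v - np.dot(v, n2) * n2
    # swing the base center from the oxygen toward the ring system
    d = frame2.center - q
    d_lat = d - np.dot(d, n2) * n2
    a_from = -v_lat / np.linalg.norm(v_lat)
    a_to = d_lat / np.linalg.norm(d_lat)
    phi = np.arctan2(float(np.dot(np.cross(a_from, a_to), n2)),
                     float(np.dot(a_from, a_to)))
    R = rotation_from_vector(phi * n2) @ R0
    t = q - R @ nt1.atoms["O4'"]
    return _renumber([transform(nt1, R, t), nt2])


def build_zstep(
    bases=("C", "G"),
    z: float = 3.0,
    xy_offset=(0.0, 0.0),
    chi1: float = -160.0,
    chi2: float = 60.0,
    pucker1: float = 162.0,
    pucker2: float = 18.0,
    stack_label: bool = False,
):
    """Two consecutive nucleotides forming a Z-step.

    Defaults plant the canonical signature: 5'-nt anti with a C2'-endo
    sugar, 3'-nt syn, and the 5' ribose O4' exactly ``z`` A above the
    centroid of the 3' base's principal ring on its 3'-face (z > 0).
    ``xy_offset`` shifts the oxygen in the 3' base plane (to plant "near"
    case-2 or negative-control geometries).
    """
    if stack_label:
        return _construct_stacked_step(bases, z, chi1, chi2, pucker1, pucker2,
                                       antiparallel=False)
    return _build_step(bases, z, xy_offset, chi1, chi2, pucker1, pucker2,
                       antiparallel=False)


def build_zanti_step(
    bases=("A", "G"),
    z: float = -3.0,
    xy_offset=(0.0, 0.0),
    chi1: float = -160.0,
    chi2: float = -130.0,
    pucker1: float = 162.0,
    pucker2: float = 18.0,
    stack_label: bool = False,
):
    """Z_anti-step: both nucleotides anti, O4' contact on the 3' base's 5'-face.

    The default 3' chi of -130 deg sits in the anti window; covalent
    closure of the synthetic step is infeasible at the canonical -160 deg
    with the idealised backbone used here.
    """
    if stack_label:
        return _construct_stacked_step(bases, z, chi1, chi2, pucker1, pucker2,
                                       antiparallel=True)
    return _build_step(bases, z, xy_offset, chi1, chi2, pucker1, pucker2,
                       antiparallel=True)


# ---------------------------------------------------------------------------
# base pairs
# ---------------------------------------------------------------------------

#: planted hydrogen bonds: (mobile atom, anchor atom, distance A, donor
#: side, donor antecedent atom), plus the relative normal orientation
#: (+1 parallel for the trans pairs here, -1 antiparallel for cis
#: Watson-Crick).  The antecedent fixes the donor approach angle.
_PAIR_GEOMETRIES = {
    # Y sugar edge onto G Watson-Crick edge: O2...N1-H plus the 2'-OH...O6 bond
    ("tSW", "U", "G"): ([("O2", "N1", 2.90, "anchor", "C6"),
                         ("O2'", "O6", 2.85, "mobile", "C2'")], +1),
    ("tSW", "C", "G"): ([("O2", "N1", 2.90, "anchor", "C6"),
                         ("O2'", "O6", 2.85, "mobile", "C2'")], +1),
    # G sugar edge onto A Watson-Crick edge
    ("tSW", "G", "A"): ([("N2", "N1", 2.95, "mobile", "C2"),
                         ("O2'", "N6", 3.00, "anchor", "C6")], +1),
    ("cWW", "C", "G"): ([("N3", "N1", 2.95, "anchor", "C6"),
                         ("O2", "N2", 2.86, "anchor", "C2"),
                         ("N4", "O6", 2.91, "mobile", "C4")], -1),
}

_WC_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}

_FLIP = np.diag([1.0, -1.0, -1.0])  # 180 deg rotation about x in template space


def _superpose_on_base(nt: NucleotideRecord, target_base_coords: dict) -> NucleotideRecord:
    """Rigid-move a nucleotide so its base atoms coincide with given coordinates."""
    names = [n for n in target_base_coords if n in nt.atoms]
    src = np.array([nt.atoms[n] for n in names])
    dst = np.array([target_base_coords[n] for n in names])
    R, t = kabsch(src, dst)
    return transform(nt, R, t)


def _anchor_frame_guesses(mobile: NucleotideRecord, anchor: NucleotideRecord,
                          first_target, normal_sign: int):
    """Initial (R, t) poses for pair placement: mobile base coplanar with the
    anchor base, first hydrogen bond roughly satisfied, in-plane spin swept."""
    fr = compute_base_frame(anchor)
    m_atom, a_atom, dist = first_target[:3]
    out = anchor.atoms[a_atom] - fr.center
    out = out - np.dot(out, fr.normal) * fr.normal
    out = out / np.linalg.norm(out)
    target_pt = anchor.atoms[a_atom] + dist * out

    n_mob = _quick_normal(mobile.atoms, mobile.base_type)
    names = list(mobile.atoms)
    center = np.mean([mobile.atoms[n] for n in names], axis=0)

    guesses = []
    # align mobile normal to +-anchor normal
    target_n = normal_sign * fr.normal
    v = np.cross(n_mob, target_n)
    s, c = np.linalg.norm(v), float(np.dot(n_mob, target_n))
    if s < 1e-9:
        R_align = np.eye(3) if c > 0 else rotation_from_vector(np.pi * fr.basis[0])
    else:
        R_align = rotation_from_vector(v / s * np.arctan2(s, c))
    for theta in np.arange(0.0, 360.0, 45.0):
        R_spin = rotation_from_vector(np.radians(theta) * target_n)
        R0 = R_spin @ R_align
        # translate so the first mobile target atom reaches its target point
        t0 = target_pt - (R0 @ (mobile.atoms[m_atom] - center))
        guesses.append((R0, t0 - center + center))  # t applied after centering
    return guesses, fr


def _place_paired(mobile: NucleotideRecord, anchor: NucleotideRecord,
                  targets, normal_sign: int, context=(), extra_score=None,
                  hbond_w: float = 8.0) -> NucleotideRecord:
    """Place ``mobile`` against ``anchor`` so the planted hydrogen bonds hold.

    ``context`` nucleotides contribute clash penalties only.
    """
    names = list(mobile.atoms)
    idx = {n: i for i, n in enumerate(names)}
    o_name, p_name, q_name = NORMAL_CONVENTION[mobile.base_type]
    i_conv = [idx[n] for n in (o_name, p_name, q_name)]
    tgt = []
    for m, a, d, side, ante in targets:
        if side == "anchor":
            tgt.append((idx[m], anchor.atoms[a], d, None, anchor.atoms[ante],
                        anchor.atoms[a]))
        else:
            tgt.append((idx[m], anchor.atoms[a], d, idx[ante], None, None))
    ctx_arrays = [np.array(list(c.atoms.values())) for c in (anchor, *context)]
    guesses, fr = _anchor_frame_guesses(mobile, anchor, targets[0], normal_sign)
    n_anchor = normal_sign * fr.normal
    hb_atoms = {m for m, *_ in targets}
    hb_rows = np.array([idx[m] for m in hb_atoms])

    def _angle_pen(ante_pos, donor_pos, acc_pos):
        v1 = ante_pos - donor_pos
        v2 = acc_pos - donor_pos
        cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
        return 0.02 * max(0.0, 120.0 - ang) ** 2

    def score(arr):
        pen = 0.0
        for i, pt, d, i_ante, ante_pos, donor_pos in tgt:
            pen += hbond_w * (np.linalg.norm(arr[i] - pt) - d) ** 2
            if i_ante is not None:  # mobile atom donates
                pen += _angle_pen(arr[i_ante], arr[i], pt)
            else:  # anchor atom donates toward the mobile acceptor
                pen += _angle_pen(ante_pos, donor_pos, arr[i])
        o, p, q = arr[i_conv]
        n1 = np.cross(p - o, q - o)
        n1 /= np.linalg.norm(n1)
        pen += 2.0 * (float(np.dot(n1, n_anchor)) - 1.0) ** 2
        for ctx in ctx_arrays:
            dd = np.linalg.norm(arr[:, None, :] - ctx[None, :, :], axis=2)
            dd[hb_rows, :] = np.maximum(dd[hb_rows, :], 2.5)
            pen += float(np.sum(np.maximum(0.0, 2.5 - dd) ** 2))
        if extra_score is not None:
            pen += extra_score(dict(zip(names, arr)))
        return pen

    placed, fun = _optimize_free(mobile, score, guesses)
    for m, a, d, *_ in targets:
        got = float(np.linalg.norm(placed.atoms[m] - anchor.atoms[a]))
        if abs(got - d) > 0.35:
            raise FixtureError(
                f"pair placement failed: {m}...{a} = {got:.2f} A (target {d})"
            )
    return placed


def build_pair(kind: str = "cWW", bases=("G", "C"), chi=(-160.0, -160.0),
               pucker=(18.0, 18.0)):
    """Two-nucleotide base-pair fixture with a planted geometry label.

    ``kind='cWW'`` produces the ideal Watson-Crick arrangement from the
    embedded planar templates (bases exactly coplanar, template hydrogen
    bond distances).  ``kind='tSW'`` plants the trans Sugar/Watson-Crick
    arrangement (e.g. U*G with the O2...N1 and 2'-OH...O6 bonds).
    Returns ``[nt1, nt2]`` ordered as named in ``bases``.
    """
    b1, b2 = bases
    nt1 = build_nucleotide(b1, chi=chi[0], pucker_P=pucker[0], seq_number=1)
    nt2 = build_nucleotide(b2, chi=chi[1], pucker_P=pucker[1], seq_number=2)
    if kind == "cWW":
        if _WC_COMPLEMENT[b1] != b2:
            raise FixtureError(f"no Watson-Crick template for {b1}={b2}")
        nt1 = _superpose_on_base(nt1, BASE_TEMPLATES[b1])
        flipped = {n: _FLIP @ x for n, x in BASE_TEMPLATES[b2].items()}
        nt2 = _superpose_on_base(nt2, flipped)
        return _renumber([nt1, nt2])
    if kind == "tSW":
        geom = _PAIR_GEOMETRIES.get(("tSW", b1, b2))
        if geom is None:
            raise FixtureError(f"no tSW geometry for {b1}*{b2}")
        targets, nsign = geom
        if b2 == "G" and chi[1] == -160.0:
            # the G of a tSW Y*G pair is syn in Z-turns; make that the default
            nt2 = build_nucleotide(b2, chi=60.0, pucker_P=pucker[1], seq_number=2)
        nt1 = _place_paired(nt1, nt2, targets, nsign)
        return _renumber([nt1, nt2])
    raise FixtureError(f"unknown pair kind {kind!r}")


# ---------------------------------------------------------------------------
# Z-turns
# ---------------------------------------------------------------------------


def _place_free_bonds(nt: NucleotideRecord, bond_targets, context,
                      max_miss: float = 0.3) -> NucleotideRecord:
    """6-dof placement satisfying (atom, point, distance) bond targets with
    clash avoidance against ``context`` nucleotides."""
    names = list(nt.atoms)
    idx = {n: i for i, n in enumerate(names)}
    tgt = [(idx[a], np.asarray(p), d) for a, p, d in bond_targets]
    ctx_arrays = [np.array(list(c.atoms.values())) for c in context]
    bond_rows = np.array([t[0] for t in tgt])

    center = np.mean([nt.atoms[n] for n in names], axis=0)
    mid_atoms = np.mean([nt.atoms[names[i]] for i, _, _ in tgt], axis=0)
    mid_targets = np.mean([p for _, p, _ in tgt], axis=0)
    guesses = [(rotation_from_vector(rv), mid_targets - (rotation_from_vector(rv) @ (mid_atoms - center)))
               for rv in _ROT_STARTS]

    def score(arr):
        pen = 0.0
        for i, pt, d in tgt:
            pen += 8.0 * (np.linalg.norm(arr[i] - pt) - d) ** 2
        for ctx in ctx_arrays:
            dd = np.linalg.norm(arr[:, None, :] - ctx[None, :, :], axis=2)
            dd[bond_rows, :] = np.maximum(dd[bond_rows, :], 2.5)
            pen += float(np.sum(np.maximum(0.0, 2.5 - dd) ** 2))
        return pen

    placed, fun = _optimize_free(nt, score, guesses)
    for i, pt, d in tgt:
        got = float(np.linalg.norm(placed.atoms[names[i]] - pt))
        if abs(got - d) > max_miss:
            raise FixtureError(
                f"bridge placement failed: {names[i]} at {got:.2f} A (target {d})"
            )
    return placed


def _build_turn(loop: str, stems, pair_kind: str, anti_variant: bool,
                break_pair: bool = False):
    """Six-nucleotide turn: stem nt, four loop nts, stem nt.

    The 3rd/4th loop residues form the planted step (Z-step, or Z_anti-step
    for the anti variant); the 1st/4th loop residues form the planted
    closing pair; chain continuity (O3'-P adjacency) holds along all five
    steps.
    """
    if anti_variant:
        n4, n5 = build_zanti_step(bases=(loop[2], loop[3]))
    else:
        n4, n5 = build_zstep(bases=(loop[2], loop[3]))

    geom = _PAIR_GEOMETRIES.get((pair_kind, loop[0], loop[3]))
    if geom is None:
        raise FixtureError(f"no {pair_kind} geometry for {loop[0]}*{loop[3]}")
    targets, nsign = geom
    n2 = build_nucleotide(loop[0], chi=-160.0, pucker_P=18.0)

    p_c4 = n4.atoms["P"]

    def bridge_window(coords):
        d = float(np.linalg.norm(coords["O3'"] - p_c4))
        return 2.0 * (max(0.0, d - 7.5) ** 2 + max(0.0, 4.0 - d) ** 2)

    n2 = _place_paired(n2, n5, targets, nsign, context=(n4,), extra_score=bridge_window)

    n3 = build_nucleotide(loop[1], chi=-160.0, pucker_P=162.0)
    n3 = _place_free_bonds(
        n3,
        [("P", n2.atoms["O3'"], 1.6), ("O3'", n4.atoms["P"], 1.6)],
        context=(n2, n4, n5),
    )

    s1 = build_nucleotide(stems[0], chi=-160.0, pucker_P=18.0)
    s1 = _place_free_bonds(s1, [("O3'", n2.atoms["P"], 1.6)], context=(n2, n3, n5))
    s6 = build_nucleotide(stems[1], chi=-160.0, pucker_P=18.0)
    s6 = _place_free_bonds(s6, [("P", n5.atoms["O3'"], 1.6)], context=(n5, n4, s1))

    records = _renumber([s1, n2, n3, n4, n5, s6])
    if break_pair:
        fr = compute_base_frame(records[4])
        records[4] = transform(records[4], np.eye(3), 5.0 * fr.normal)
    return records


def build_uncg_zturn(loop: str = "UUCG", stems=("G", "C"), break_pair: bool = False):
    """Planted r(UNCG)-type Z-turn: stem nt + UNCG loop + stem nt.

    Carries a tSW U*G closing pair, a CpG Z-step between the 3rd and 4th
    loop residues (sO4'3 contact), and full 5'->3' chain continuity.
    ``break_pair`` displaces the loop G by 5 A as a negative control.
    """
    if not (len(loop) == 4 and loop[0] in "UC" and loop[3] == "G"):
        raise FixtureError(f"not a UNCG-type loop: {loop!r}")
    return _build_turn(loop, stems, "tSW", anti_variant=False, break_pair=break_pair)


def build_gnna_zturn(loop: str = "GAAA", stems=("C", "G"), break_pair: bool = False):
    """Planted r(GNNA)-type Z-turn with a tSW G*A pair and an NpA Z-step."""
    if not (len(loop) == 4 and loop[0] == "G" and loop[3] == "A"):
        raise FixtureError(f"not a GNNA-type loop: {loop!r}")
    return _build_turn(loop, stems, "tSW", anti_variant=False, break_pair=break_pair)


def build_cnng_zanti_turn(loop: str = "CUUG", stems=("G", "C"),
                          break_pair: bool = False):
    """Planted r(CNNG) Z_anti-turn: cWW C=G pair, sO4'5 contact, loop G anti."""
    if not (len(loop) == 4 and loop[0] == "C" and loop[3] == "G"):
        raise FixtureError(f"not a CNNG-type loop: {loop!r}")
    return _build_turn(loop, stems, "cWW", anti_variant=True, break_pair=break_pair)


# ---------------------------------------------------------------------------
# helical fixtures
# ---------------------------------------------------------------------------


def _screw(twist_deg: float, rise: float, axis_xy) -> tuple[np.ndarray, np.ndarray]:
    """(R, t) of a screw motion about a vertical axis through ``axis_xy``."""
    c, s = np.cos(np.radians(twist_deg)), np.sin(np.radians(twist_deg))
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    a = np.array([axis_xy[0], axis_xy[1], 0.0])
    t = a - R @ a + np.array([0.0, 0.0, rise])
    return R, t


def build_aform_duplex(sequence: str = "GGCGCC", twist: float = 32.7,
                       rise: float = 2.81):
    """Ideal A-form-like double helix with Watson-Crick pairs at every step.

    Strand A runs 5'->3' with the given sequence; strand B is its reverse
    complement.  Bases sit exactly on the helically-transformed planar
    templates (so every pair is an ideal cis Watson-Crick pair); the screw
    axis and backbone torsions are fitted once so that consecutive
    residues of both strands are covalently plausible (O3'-P within the
    2.0 A adjacency criterion).
    """
    n = len(sequence)
    comp = "".join(_WC_COMPLEMENT[b] for b in reversed(sequence))
    # twist/rise are given in the 5'->3' sense; with the planar templates in
    # the z = 0 plane the chain's 3' direction is -z, so the physical screw
    # advances by -rise per step (twist keeps its sign about +z)
    rise = -rise

    proto_cache: dict = {}

    def protos(chi, P):
        key = (round(chi, 4), round(P, 4))
        if key not in proto_cache:
            p1 = _superpose_on_base(build_nucleotide("G", chi=chi, pucker_P=P),
                                    BASE_TEMPLATES["G"])
            p2 = _superpose_on_base(
                build_nucleotide("C", chi=chi, pucker_P=P),
                {k: _FLIP @ v for k, v in BASE_TEMPLATES["C"].items()},
            )
            proto_cache[key] = (p1, p2)
        return proto_cache[key]

    # The helical axis is constrained to the pair pseudo-dyad (the x axis
    # of the template frame): conjugating the screw by the strand flip then
    # maps strand A onto strand B, so one closure condition serves both
    # strands.  Backbone torsions, chi, pucker and the axis position along
    # the dyad are fitted jointly, once.
    def _incline(eta):
        e = np.radians(eta)
        c, sn = np.cos(e), np.sin(e)
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -sn], [0.0, sn, c]])

    def closure(params):
        g, b, chi, P, ax, eta = params
        if not (-179.0 < chi < -120.0 and 5.0 < P < 40.0 and -45.0 < eta < 45.0):
            return 100.0
        p1, p2 = protos(chi, P)
        set_backbone(p1, gamma=54.0 + g, beta=180.0 + b)
        set_backbone(p2, gamma=54.0 + g, beta=180.0 + b)
        Re = _incline(eta)
        R, t = _screw(twist, rise, (ax, 0.0))
        d1 = np.linalg.norm((R @ (Re @ p1.atoms["P"]) + t) - Re @ p1.atoms["O3'"])
        d2 = np.linalg.norm((R @ (Re @ p2.atoms["O3'"]) + t) - Re @ p2.atoms["P"])
        return (d1 - 1.6) ** 2 + 0.2 * (d2 - 1.6) ** 2

    # the first start is a solved configuration for the default twist/rise;
    # the grid behind it keeps the fit robust for other helical parameters
    starts = [np.array([-6.407952, -184.477529, -157.596855, 5.000409, -3.146821, -4.077143])]
    starts += [np.array([g0, b0, -160.0, 18.0, ax0, 0.0])
               for g0 in (-100.0, 0.0, 100.0)
               for b0 in (-80.0, 0.0, 80.0)
               for ax0 in (-4.0, 0.0, 4.0)]
    best = None
    for x0 in starts:
        res = minimize(closure, x0, method="Powell",
                       options={"maxiter": 4000, "xtol": 1e-6, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-8:
            break
    g1, b1, chi, P, ax, eta = best.x
    g2, b2, ay = g1, b1, 0.0
    R_eta = _incline(eta)
    if best.fun > 0.04:  # ~0.2 A residual per bond
        raise FixtureError(f"duplex backbone closure failed (fun={best.fun:.3f})")

    records = []
    for i, b in enumerate(sequence):
        nt = _superpose_on_base(
            build_nucleotide(b, chi=chi, pucker_P=P, gamma=54.0 + g1,
                             beta=180.0 + b1),
            BASE_TEMPLATES[b],
        )
        Ri, ti = _screw(twist * i, rise * i, (ax, ay))
        records.append(transform(nt, Ri @ R_eta, ti))
    _renumber(records, chain="A")

    strand_b = []
    for k, b in enumerate(comp):  # k: 5'->3' along strand B
        i = n - 1 - k  # paired strand-A index
        nt = _superpose_on_base(
            build_nucleotide(b, chi=chi, pucker_P=P, gamma=54.0 + g2,
                             beta=180.0 + b2),
            {kk: _FLIP @ v for kk, v in BASE_TEMPLATES[b].items()},
        )
        Ri, ti = _screw(twist * i, rise * i, (ax, ay))
        strand_b.append(transform(nt, Ri @ R_eta, ti))
    _renumber(strand_b, chain="B")
    return records + strand_b


def build_zhelix(n_steps: int = 3, twist: float = -60.0, rise: float = 7.25):
    """Single-stranded (CG)n Z-helix-like fixture: each CpG unit is a planted
    Z-step; units are related by a fitted left-handed dinucleotide screw so
    the strand is covalently continuous where the fit allows."""
    twist, rise = -twist, -rise  # physical screw, as in build_aform_duplex
    unit = build_zstep(bases=("C", "G"))
    c_nt, g_nt = unit
    frame_c = compute_base_frame(c_nt)

    def closure(params):
        ax, ay, tw, rs, g, b = params
        R, t = _screw(twist + tw, rise + rs, (ax, ay))
        work = transform(c_nt, np.eye(3), np.zeros(3))
        set_backbone(work, gamma=54.0 + g, beta=180.0 + b)
        d = np.linalg.norm((R @ work.atoms["P"] + t) - g_nt.atoms["O3'"])
        pen = (d - 1.6) ** 2 + 0.05 * (tw**2 + rs**2) / 100.0
        # keep the GpC junction free of incidental oxygen...pi contacts:
        # project this unit's backbone oxygens onto the next unit's C face
        c_next = R @ frame_c.center + t
        n_next = R @ frame_c.normal
        for nt in (c_nt, g_nt):
            for oxy in ("OP1", "OP2", "O2'", "O3'", "O4'", "O5'"):
                dv = nt.atoms[oxy] - c_next
                zz = float(np.dot(dv, n_next))
                lat = float(np.sqrt(max(0.0, np.dot(dv, dv) - zz * zz)))
                if abs(zz) < 4.0 and lat < 3.4:
                    pen += 0.3 * (4.0 - abs(zz)) * (3.4 - lat)
        return pen

    best = None
    for ax0, ay0 in ((0.0, 0.0), (3.0, 0.0), (-3.0, 0.0), (0.0, 3.0), (0.0, -3.0)):
        res = minimize(closure, np.array([ax0, ay0, 0.0, 0.0, 0.0, 0.0]),
                       method="Powell", options={"maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    ax, ay, tw, rs, g, b = best.x
    c_fit = transform(c_nt, np.eye(3), np.zeros(3))
    set_backbone(c_fit, gamma=54.0 + g, beta=180.0 + b)

    records = []
    for i in range(n_steps):
        Ri, ti = _screw((twist + tw) * i, (rise + rs) * i, (ax, ay))
        records.append(transform(c_fit, Ri, ti))
        records.append(transform(g_nt, Ri, ti))
    return _renumber(records, chain="A")


# ---------------------------------------------------------------------------
# caching and file output
# ---------------------------------------------------------------------------

_BUILD_CACHE: dict = {}


def _copy_records(records):
    return [transform(r, np.eye(3), np.zeros(3)) for r in records]


def _install_cache():
    """Memoise the deterministic builders (they involve small optimisations)."""
    import functools

    def cached(fn):
        @functools.wraps(fn)
        def wrapper(*args, **kwargs):
            key = (fn.__name__, repr(args), repr(sorted(kwargs.items())))
            if key not in _BUILD_CACHE:
                _BUILD_CACHE[key] = fn(*args, **kwargs)
            return _copy_records(_BUILD_CACHE[key])

        return wrapper

    g = globals()
    for name in ("build_zstep", "build_zanti_step", "build_pair",
                 "build_uncg_zturn", "build_gnna_zturn", "build_cnng_zanti_turn",
                 "build_aform_duplex", "build_zhelix"):
        g[name] = cached(g[name])


_install_cache()


def write_fixture(records, path, fmt: str = "auto"):
    """Write fixture records as a minimal PDB or mmCIF file (via gemmi).

    ``fmt='auto'`` picks the dialect from the file suffix (.pdb / .cif).
    """
    import gemmi

    path = str(path)
    if fmt == "auto":
        fmt = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    st = gemmi.Structure()
    st.name = records[0].structure_id if records else "FIXTURE"
    by_model: dict[int, dict[str, list]] = {}
    for rec in records:
        by_model.setdefault(rec.model, {}).setdefault(rec.chain, []).append(rec)
    for model_num in sorted(by_model):
        model = gemmi.Model(model_num)
        for chain_name in sorted(by_model[model_num]):
            chain = gemmi.Chain(chain_name)
            for rec in sorted(by_model[model_num][chain_name],
                              key=lambda r: (r.seq_number, r.insertion_code)):
                res = gemmi.Residue()
                res.name = ("D" + rec.base_type) if rec.is_dna else rec.base_type
                res.seqid = gemmi.SeqId(rec.seq_number, rec.insertion_code or " ")
                for name, xyz in rec.atoms.items():
                    atom = gemmi.Atom()
                    atom.name = name
                    atom.pos = gemmi.Position(*np.round(xyz, 3))
                    atom.occ = rec.occupancy.get(name, 1.0)
                    atom.altloc = rec.altloc.get(name, "") or "\0"
                    atom.element = gemmi.Element(name[0])
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(path)
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
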