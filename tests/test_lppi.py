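"""Lone-pair...pi contact annotation: cases, selection rules, constraints."""

import numpy as np
import pytest

from conftest import make_base_record, moved, random_rigid_motion
from oracles import lppi_oracle
from zmotif.base_frames import compute_base_frame
from zmotif.lppi import (
    ConstraintError,
    LpPiParameters,
    annotate_pair,
    match_constraint,
    parse_constraint,
    scan_structure,
)
from zmotif.records import NucleotideRecord
from zmotif.reference import STANDARD_BASES


def oxygen_owner(positions, seq=2):
    """Record carrying only backbone oxygens at the given positions."""
    return NucleotideRecord(
        structure_id="TEST", model=1, chain="A", seq_number=seq,
        insertion_code="", base_type="U",
        atoms={k: np.asarray(v, dtype=float) for k, v in positions.items()},
    )


@pytest.fixture(scope="module")
def g_frame():
    rec = make_base_record("G")
    return rec, compute_base_frame(rec)


class TestAnnotatePair:
    def test_axial_true_contact(self, g_frame):
        rec, frame = g_frame
        cen = frame.ring_polygons[0].mean(axis=0)
        pos = frame.unproject(cen[0], cen[1], 3.0)
        ann = annotate_pair(rec, frame, oxygen_owner({"O4'": pos}))
        assert ann is not None
        assert (ann.category, ann.face) == ("true", 3)
        assert ann.oxygen_first_string == "sO4′3"
        assert ann.base_first_string == "s3O4′"

    def test_case1_near_band(self, g_frame):
        rec, frame = g_frame
        cen = frame.ring_polygons[0].mean(axis=0)
        pos = frame.unproject(cen[0], cen[1], 3.55)
        ann = annotate_pair(rec, frame, oxygen_owner({"O4'": pos}))
        assert ann.category == "near"
        assert ann.oxygen_first_string == "nsO4′3"

    def test_in_plane_exclusion(self, g_frame):
        """|z| below 2.0 A is an in-plane contact, not a stacking contact."""
        rec, frame = g_frame
        cen = frame.ring_polygons[0].mean(axis=0)
        pos = frame.unproject(cen[0], cen[1], 1.5)
        assert annotate_pair(rec, frame, oxygen_owner({"O4'": pos})) is None

    def test_five_prime_face_sign(self, g_frame):
        rec, frame = g_frame
        cen = frame.ring_polygons[0].mean(axis=0)
        pos = frame.unproject(cen[0], cen[1], -3.0)
        ann = annotate_pair(rec, frame, oxygen_owner({"O4'": pos}))
        assert (ann.face, ann.oxygen_first_string) == (5, "sO4′5")

    def test_smallest_abs_z_wins(self, g_frame):
        rec, frame = g_frame
        cen = frame.ring_polygons[0].mean(axis=0)
        owner = oxygen_owner({
            "O2'": frame.unproject(cen[0], cen[1], 3.2),
            "O5'": frame.unproject(cen[0] + 0.2, cen[1], 2.9),
        })
        ann = annotate_pair(rec, frame, owner)
        assert ann.oxygen_atom == "O5'"
        assert ann.z == pytest.approx(2.9)

    def test_intra_nucleotide_excluded_by_default(self, g_frame):
        rec, frame = g_frame
        cen = frame.ring_polygons[0].mean(axis=0)
        rec2 = make_base_record("G")
        rec2.atoms["O4'"] = frame.unproject(cen[0], cen[1], 3.0)
        assert annotate_pair(rec2, frame, rec2) is None
        params = LpPiParameters(include_intra=True)
        assert annotate_pair(rec2, frame, rec2, params) is not None

    @pytest.mark.parametrize("base", STANDARD_BASES)
    def test_matches_bruteforce_oracle(self, base, rng):
        """>=10^4 randomised oxygen placements per base classify identically
        to the exhaustive (oxygen, ring, case) enumeration oracle."""
        rec = make_base_record(base)
        frame = compute_base_frame(rec)
        params = LpPiParameters()
        names = list(params.oxygen_atoms)
        n_rounds = 10_000 // 4  # four oxygens per round -> 10^4 placements
        for _ in range(n_rounds):
            chosen = rng.choice(names, size=4, replace=False)
            positions = {}
            for name in chosen:
                xy = rng.uniform(-3.5, 3.5, size=2)
                z = rng.uniform(-4.2, 4.2)
                positions[name] = frame.unproject(xy[0], xy[1], z)
            owner = oxygen_owner(positions)
            got = annotate_pair(rec, frame, owner, params)
            want = lppi_oracle(frame, positions, params)
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert (got.oxygen_atom, got.category, got.face) == want


class TestScanInvariants:
    def test_zstep_fixture_single_contact(self, zstep):
        annos = scan_structure(zstep)
        assert len(annos) == 1
        assert annos[0].oxygen_first_string == "sO4′3"
        assert annos[0].base_nt.seq_number == 2
        assert annos[0].oxygen_nt.seq_number == 1

    def test_empty_input(self):
        assert scan_structure([]) == []

    def test_direction_mirror_strings(self, zstep):
        # the two directional strings name the same face and oxygen
        ann = scan_structure(zstep)[0]
        assert ann.base_first_string == f"s{ann.face}O4′"
        assert ann.oxygen_first_string == f"sO4′{ann.face}"

    def test_shrinking_true_band_never_adds_contacts(self, uncg_zturn):
        wide = {(a.base_nt, a.oxygen_nt) for a in scan_structure(uncg_zturn)
                if a.category == "true"}
        narrow_params = LpPiParameters(z_max_true=3.2, z_max_near=3.6)
        narrow = {(a.base_nt, a.oxygen_nt) for a in
                  scan_structure(uncg_zturn, narrow_params) if a.category == "true"}
        assert narrow <= wide

    def test_near_flag_conserves_true_contacts(self, zhelix):
        with_near = scan_structure(zhelix, near=True)
        true_only = scan_structure(zhelix, near=False)
        true_subset = [a for a in with_near if a.category == "true"]
        assert [(a.base_nt, a.oxygen_nt) for a in true_subset] == \
            [(a.base_nt, a.oxygen_nt) for a in true_only]
        assert len(with_near) >= len(true_only)

    def test_face_flip_under_reflection(self, zstep, rng):
        """Reflecting the structure through the base plane swaps face 3 and 5.

        A mirror image is realised as a proper rotation of the mirrored
        coordinate triple; chirality-sensitive quantities are not compared,
        only the face label, which must flip.
        """
        before = scan_structure(zstep)[0]
        frame = compute_base_frame(zstep[1])
        n, c = frame.normal, frame.center
        mirrored = []
        for rec in zstep:
            new = moved(rec, np.eye(3), np.zeros(3))
            for a, v in new.atoms.items():
                d = v - c
                new.atoms[a] = c + d - 2.0 * np.dot(d, n) * n
            mirrored.append(new)
        after = scan_structure(mirrored)[0]
        assert before.face == 3
        assert after.face == 5
        assert after.oxygen_atom == before.oxygen_atom


class TestConstraints:
    @pytest.mark.parametrize(
        "text,near,face,oxy,base_first",
        [
            ("sO", "true", None, "O", False),
            ("sOP", "true", None, "OP", False),
            ("sO4′3", "true", 3, "O4'", False),
            ("sO4'3", "true", 3, "O4'", False),
            ("s3O4′", "true", 3, "O4'", True),
            ("nsO4′3", "near", 3, "O4'", False),
            ("n+sO4′3", "both", 3, "O4'", False),
            ("sO3", "true", 3, "O", False),
            ("s5OP2", "true", 5, "OP2", True),
        ],
    )
    def test_parse_grammar(self, text, near, face, oxy, base_first):
        c = parse_constraint(text)
        assert (c.near_mode, c.face, c.oxygen, c.base_first) == (near, face, oxy, base_first)

    @pytest.mark.parametrize("bad", ["s", "xO4′3", "s3O4′5", "sO6′3", "nsQ", ""])
    def test_malformed_constraints_rejected(self, bad):
        with pytest.raises(ConstraintError) as err:
            parse_constraint(bad)
        assert "position" in str(err.value)

    def test_matching_semantics(self, zstep):
        ann = scan_structure(zstep)[0]  # true sO4'3
        assert match_constraint(ann, "sO")
        assert match_constraint(ann, "sO4′3")
        assert match_constraint(ann, "sO3")
        assert not match_constraint(ann, "sO5")
        assert not match_constraint(ann, "sOP")
        assert not match_constraint(ann, "nsO4′3")
        assert match_constraint(ann, "n+sO4′3")

    def test_near_annotation_matching(self):
        from zmotif.fixtures import build_zstep

        near_step = build_zstep(z=3.55)
        ann = scan_structure(near_step)[0]
        assert ann.category == "near"
        assert not match_constraint(ann, "sO4′3")
        assert match_constraint(ann, "n+sO4′3")
        assert match_constraint(ann, "nsO4′3")
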