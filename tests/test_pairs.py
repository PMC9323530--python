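"""Hydrogen bonds, Leontis-Westhof families, stacking faces."""

import numpy as np
import pytest

from conftest import make_base_record
from zmotif.fixtures import build_nucleotide, build_pair, build_zstep, transform, _construct_stacked_step
from zmotif.base_frames import compute_base_frame
from zmotif.geometry import angle
from zmotif.pairs import PairParameters, classify_lw, classify_stack, detect_hbonds
from zmotif.records import NucleotideRecord
from zmotif.reference import HBOND_ACCEPTORS, HBOND_DONORS


class TestHBonds:
    def test_ideal_watson_crick_gc_has_three_true_bonds(self, cww_gc_pair):
        hb = [h for h in detect_hbonds(*cww_gc_pair) if not h.near]
        assert len(hb) == 3
        pairs = {(h.donor_atom, h.acceptor_atom) for h in hb}
        assert pairs == {("N1", "N3"), ("N2", "O2"), ("N4", "O6")}

    def test_distant_bases_no_bonds(self):
        a = make_base_record("G", seq=1)
        b = make_base_record("C", seq=2)
        b = NucleotideRecord(
            structure_id="TEST", model=1, chain="A", seq_number=2,
            insertion_code="", base_type="C",
            atoms={k: v + np.array([10.0, 0, 0]) for k, v in b.atoms.items()},
        )
        assert detect_hbonds(a, b) == []

    def test_matches_bruteforce_all_pairs_oracle(self, rng):
        """Randomised near-contact geometries agree with a brute-force
        enumeration using the same distance and angle thresholds."""
        params = PairParameters()
        for _ in range(50):
            a = make_base_record("G", seq=1)
            b = make_base_record("U", seq=2)
            shift = rng.uniform(-1.5, 1.5, size=3) + np.array([0.0, -6.5, 0.0])
            b = NucleotideRecord(
                structure_id="TEST", model=1, chain="A", seq_number=2,
                insertion_code="", base_type="U",
                atoms={k: v + shift for k, v in b.atoms.items()},
            )
            got = {(h.donor_nt.seq_number, h.donor_atom, h.acceptor_atom)
                   for h in detect_hbonds(a, b, params)}
            want = set()
            for x, y in ((a, b), (b, a)):
                for d_atom, ante in HBOND_DONORS[x.base_type].items():
                    if d_atom not in x.atoms:
                        continue
                    for acc in HBOND_ACCEPTORS[y.base_type]:
                        if acc not in y.atoms:
                            continue
                        dist = np.linalg.norm(x.atoms[d_atom] - y.atoms[acc])
                        if not (2.2 <= dist <= params.hbond_near_max):
                            continue
                        if angle(x.atoms[ante], x.atoms[d_atom], y.atoms[acc]) \
                                < params.hbond_min_angle:
                            continue
                        want.add((x.seq_number, d_atom, acc))
            assert got == want


class TestClassifyLW:
    def test_ideal_cww_gc(self, cww_gc_pair):
        ann = classify_lw(*cww_gc_pair)
        assert (ann.family, ann.orientation, ann.near) == ("cWW", "cis", False)

    def test_planted_tsw_ug(self, tsw_ug_pair):
        """The revised U*G arrangement: U sugar edge (O2, 2'-OH) against the
        G Watson-Crick edge, trans orientation."""
        ann = classify_lw(*tsw_ug_pair)
        assert (ann.family, ann.orientation) == ("tSW", "trans")
        bonded = {(h.donor_atom, h.acceptor_atom) for h in ann.hbonds if not h.near}
        assert ("N1", "O2") in bonded  # G N1-H ... O2(U)
        assert ("O2'", "O6") in bonded  # U 2'-OH ... O6(G)

    def test_symmetry_transposes_edges(self, tsw_ug_pair, cww_gc_pair):
        u, g = tsw_ug_pair
        assert classify_lw(g, u).family == "tWS"
        a, b = cww_gc_pair
        assert classify_lw(b, a).family == "cWW"

    def test_no_pair_for_distant_bases(self):
        a = make_base_record("U", seq=1)
        b = make_base_record("G", seq=2)
        for k in b.atoms:
            b.atoms[k] = b.atoms[k] + np.array([20.0, 0.0, 0.0])
        assert classify_lw(a, b) is None

    def test_duplex_all_cww_no_tsw(self, aform_duplex):
        by_chain = {}
        for r in aform_duplex:
            by_chain.setdefault(r.chain, []).append(r)
        A = sorted(by_chain["A"], key=lambda r: r.seq_number)
        B = sorted(by_chain["B"], key=lambda r: r.seq_number)
        fams = [classify_lw(a, b).family for a, b in zip(A, reversed(B))]
        assert fams == ["cWW"] * len(A)

    def test_turn_closing_pairs(self, uncg_zturn, gnna_zturn, cnng_zanti_turn):
        assert classify_lw(uncg_zturn[1], uncg_zturn[4]).family == "tSW"
        assert classify_lw(gnna_zturn[1], gnna_zturn[4]).family == "tSW"
        cww = classify_lw(cnng_zanti_turn[1], cnng_zanti_turn[4])
        assert (cww.family, cww.orientation) == ("cWW", "cis")


class TestClassifyStack:
    def test_translated_parallel_bases_stack(self):
        nt1 = build_nucleotide("G", chi=-160.0)
        f = compute_base_frame(nt1)
        nt2 = transform(nt1, np.eye(3), 3.4 * f.normal)
        nt2.seq_number = 2
        ann = classify_stack(nt1, nt2)
        assert ann is not None and not ann.near
        # same-normal translation engages nt1's 3'-face and nt2's 5'-face
        assert ann.faces == "s35"
        assert ann.z_offset == pytest.approx(3.4, abs=1e-6)

    def test_coplanar_bases_do_not_stack(self):
        nt1 = build_nucleotide("G")
        f = compute_base_frame(nt1)
        nt2 = transform(nt1, np.eye(3), 8.0 * f.basis[0])
        assert classify_stack(nt1, nt2) is None

    def test_zstep_label_is_s53(self):
        step = build_zstep(stack_label=True)
        ann = classify_stack(*step)
        assert ann is not None
        assert ann.faces == "s53"

    def test_zanti_label_is_s55(self):
        step = _construct_stacked_step(("U", "G"), -3.0, -160.0, -130.0,
                                       162.0, 162.0, True)
        ann = classify_stack(*step)
        assert ann is not None
        assert ann.faces == "s55"

    def test_faces_transpose_on_argument_swap(self):
        nt1 = build_nucleotide("A")
        f = compute_base_frame(nt1)
        nt2 = transform(nt1, np.eye(3), 3.4 * f.normal)
        nt2.seq_number = 2
        a = classify_stack(nt1, nt2)
        b = classify_stack(nt2, nt1)
        assert a.faces == "s35" and b.faces == "s53"
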