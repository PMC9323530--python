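"""Symbolic query engine and canned Z-step / Z-turn searches."""

import numpy as np
import pytest

from zmotif import AnnotatedStructure
from zmotif.fixtures import (
    build_uncg_zturn,
    build_zstep,
    perturb,
    transform,
)
from zmotif.motifs import (
    MotifQuery,
    QueryError,
    find_zanti_steps,
    find_zsteps,
    find_zturns,
    mutual_similarity_matrix,
    run_query,
    survey_checks,
    zturn_query,
)


class TestRunQuery:
    def test_invalid_node_reference_rejected_before_scan(self):
        q = MotifQuery(n_nodes=2, chi_constraints={5: "syn"})
        with pytest.raises(QueryError):
            run_query(q, [])

    def test_malformed_lppi_constraint_rejected(self):
        q = MotifQuery(n_nodes=2, lppi_constraints={(1, 2): "sQ9"})
        with pytest.raises(Exception):
            run_query(q, [])

    def test_empty_structure_list(self):
        q = zturn_query("UNNG", "loose")
        assert run_query(q, []) == []

    def test_planted_turn_found_and_validates(self, uncg_zturn):
        st = AnnotatedStructure(uncg_zturn)
        hits = find_zturns([st], "UNNG", "strict")
        assert len(hits) == 1
        hit = hits[0]
        assert hit.sequence == "GUUCGC"
        # replay every constraint of the strict query against annotations
        q = zturn_query("UNNG", "strict")
        keys = hit.keys
        for (i, j), text in q.lppi_constraints.items():
            from zmotif.lppi import parse_constraint

            ann = st.lppi_for(keys[i - 1], keys[j - 1])
            assert ann is not None and parse_constraint(text).matches(ann)
        for node, want in q.chi_constraints.items():
            assert st.chi(keys[node - 1]).cls == want
        pair = st.pair(keys[1], keys[4])
        assert pair is not None and pair.family == "tSW"

    def test_broken_pair_negative_control(self):
        broken = build_uncg_zturn(break_pair=True)
        assert find_zturns([AnnotatedStructure(broken)], "UNNG", "loose") == []

    def test_hit_deduplication_is_per_structure(self, uncg_zturn):
        st = AnnotatedStructure(uncg_zturn)
        assert len(run_query(zturn_query("UNNG", "loose"), [st])) == 1
        # listing a structure twice surveys it twice; duplicates are only
        # merged within one structure
        assert len(run_query(zturn_query("UNNG", "loose"), [st, st])) == 2


class TestZSteps:
    def test_zhelix_one_hit_per_cpg_step(self, zhelix):
        hits = find_zsteps(AnnotatedStructure(zhelix))
        assert [h.step_sequence for h in hits] == ["CpG", "CpG", "CpG"]
        assert [h.keys[0].seq_number for h in hits] == [1, 3, 5]

    def test_aform_duplex_negative_control(self, aform_duplex):
        assert find_zsteps(AnnotatedStructure(aform_duplex)) == []

    def test_strict_hits_carry_required_annotations(self, zhelix):
        """Wiring guard: every strict hit has an sO4'3 contact and a
        C2'-endo 5' sugar by construction of the query."""
        st = AnnotatedStructure(zhelix)
        for hit in find_zsteps(st):
            k1, k2 = hit.keys
            ann = st.lppi_for(k1, k2)
            assert ann is not None
            assert ann.oxygen_atom == "O4'" and ann.face == 3
            assert st.sugar(k1).cls == "C2'-endo"
            assert st.chi(k2).cls == "syn"

    def test_zanti_finder_disjoint_from_zstep_finder(self, zstep, zanti_step):
        st_z = AnnotatedStructure(zstep)
        st_a = AnnotatedStructure(zanti_step)
        assert len(find_zsteps(st_z)) == 1
        assert find_zanti_steps(st_z) == []
        assert len(find_zanti_steps(st_a)) == 1
        assert find_zsteps(st_a) == []


class TestZTurns:
    def test_loose_and_strict_on_planted_turn(self, uncg_zturn):
        st = AnnotatedStructure(uncg_zturn)
        assert len(find_zturns([st], "UNNG", "loose")) == 1
        assert len(find_zturns([st], "UNNG", "strict")) == 1

    def test_gnna_template(self, gnna_zturn):
        st = AnnotatedStructure(gnna_zturn)
        assert len(find_zturns([st], "GNNA", "strict")) == 1
        assert find_zturns([st], "UNNG", "loose") == []

    def test_cnng_zanti_template(self, cnng_zanti_turn):
        st = AnnotatedStructure(cnng_zanti_turn)
        assert len(find_zturns([st], "zanti_CNNG", "strict")) == 1
        # the anti-variant does not match the Z-turn template: the loop G
        # is anti and carries an sO4'5, not an sO4'3, contact
        assert find_zturns([st], "CNNG", "strict") == []

    def test_unknown_template_rejected(self):
        with pytest.raises(QueryError):
            zturn_query("XXXX")

    def test_strict_subset_of_loose_on_randomised_batches(self, uncg_zturn, rng):
        """Constraint monotonicity under coordinate noise."""
        for seed in range(8):
            noisy = perturb(uncg_zturn, sigma=0.12, seed=seed)
            st = AnnotatedStructure(noisy)
            loose = {h.keys for h in find_zturns([st], "UNNG", "loose")}
            strict = {h.keys for h in find_zturns([st], "UNNG", "strict")}
            assert strict <= loose

    def test_near_pairs_widen_hits(self, uncg_zturn):
        st = AnnotatedStructure(uncg_zturn)
        plain = {h.keys for h in find_zturns([st], "UNNG", "loose")}
        widened = {h.keys for h in find_zturns([st], "UNNG", "loose", near_pairs=True)}
        assert plain <= widened


class TestSimilarityMatrix:
    def _hits(self, st):
        return find_zsteps(st)

    def test_duplicate_hit_zero_offdiagonal(self, zstep):
        st = AnnotatedStructure(zstep)
        h = self._hits(st)[0]
        m = mutual_similarity_matrix([h, h])
        assert m.shape == (2, 2)
        np.testing.assert_allclose(m, 0.0, atol=1e-9)

    def test_superposition_invariance(self, zstep, rng):
        from conftest import random_rigid_motion

        st = AnnotatedStructure(zstep)
        h = self._hits(st)[0]
        R, t = random_rigid_motion(rng)
        movedrecs = [transform(r, R, t) for r in zstep]
        h2 = self._hits(AnnotatedStructure(movedrecs))[0]
        m = mutual_similarity_matrix([h, h2])
        assert m[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_rigid_shift_gives_zero(self, zstep):
        st = AnnotatedStructure(zstep)
        h = self._hits(st)[0]
        shifted = [transform(r, np.eye(3), np.array([1.0, 0, 0])) for r in zstep]
        h2 = self._hits(AnnotatedStructure(shifted))[0]
        m = mutual_similarity_matrix([h, h2])
        assert m[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_known_perturbation_matches_independent_superposition(self, zstep):
        """Perturbing one base by a known 1.0 A shift yields exactly the RMSD
        computed by an independent superposition routine (scipy
        align_vectors) on the same matched atoms."""
        from scipy.spatial.transform import Rotation

        from zmotif.reference import base_heavy_atoms

        st = AnnotatedStructure(zstep)
        h = self._hits(st)[0]
        perturbed = [transform(r, np.eye(3), np.zeros(3)) for r in zstep]
        shift = np.array([0.25, 0.0, 0.0])  # small enough to keep the hit alive
        for name in perturbed[1].atoms:
            perturbed[1].atoms[name] = perturbed[1].atoms[name] + shift
        h2 = self._hits(AnnotatedStructure(perturbed))[0]
        m = mutual_similarity_matrix([h, h2])

        def coords(hit):
            pts = []
            for nt in hit.nucleotides:
                for a in ["C1'"] + base_heavy_atoms(nt.base_type):
                    pts.append(nt.atoms[a])
            return np.array(pts)

        a, b = coords(h), coords(h2)
        ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
        rot, rssd = Rotation.align_vectors(bc, ac)
        expected = rssd / np.sqrt(len(a))
        assert m[0, 1] == pytest.approx(expected, abs=1e-9)
        assert m[0, 1] > 0.02  # the perturbation is visible

    def test_mismatched_node_counts_rejected(self, zstep, uncg_zturn):
        st1 = AnnotatedStructure(zstep)
        st2 = AnnotatedStructure(uncg_zturn)
        h1 = find_zsteps(st1)[0]
        h2 = find_zturns([st2], "UNNG", "loose")[0]
        with pytest.raises(ValueError):
            mutual_similarity_matrix([h1, h2])


class TestSurveyChecks:
    def test_clean_survey_no_warnings(self, zhelix):
        hits = find_zsteps(AnnotatedStructure(zhelix))
        assert survey_checks(hits) == []

    def test_modal_and_forbidden_sequence_warnings(self):
        class FakeHit:
            def __init__(self, seq):
                self.step_sequence = seq

        warns = survey_checks([FakeHit("ApA"), FakeHit("ApA"), FakeHit("CpC")])
        assert any("modal" in w for w in warns)
        assert any("CpC" in w for w in warns)
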