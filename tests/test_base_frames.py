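"""Base frames: plane fit, signed normal, ring ellipses and projections."""

import numpy as np
import pytest

from conftest import make_base_record, moved, random_rigid_motion
from oracles import (
    best_three_point_plane_residual,
    frame_oracle,
    locate_oracle,
    plane_fit_residual,
)
from zmotif.base_frames import (
    FrameError,
    compute_base_frame,
    fit_ring_ellipse,
    locate_projection,
)
from zmotif.reference import ALL_RING_ATOMS, STANDARD_BASES, base_heavy_atoms


class TestFrame:
    @pytest.mark.parametrize("base", STANDARD_BASES)
    def test_center_is_mean_of_base_heavy_atoms(self, base):
        rec = make_base_record(base)
        frame = compute_base_frame(rec)
        expected = np.mean([rec.atoms[a] for a in base_heavy_atoms(base)], axis=0)
        np.testing.assert_allclose(frame.center, expected, atol=1e-12)

    @pytest.mark.parametrize("base", STANDARD_BASES)
    def test_plane_beats_every_three_atom_plane(self, base, rng):
        """The TLS plane RMS residual is no worse than any plane through 3 ring atoms."""
        rec = make_base_record(base)
        # buckle the base slightly so the fit is non-trivial
        for a in rec.atoms:
            rec.atoms[a] = rec.atoms[a] + np.array([0, 0, rng.normal(0, 0.05)])
        frame = compute_base_frame(rec)
        pts = np.array([rec.atoms[a] for a in ALL_RING_ATOMS[base]])
        res = plane_fit_residual(pts, frame.normal, pts.mean(axis=0))
        assert res <= best_three_point_plane_residual(pts) + 1e-9

    @pytest.mark.parametrize("base", STANDARD_BASES)
    def test_normal_sign_invariant_under_rigid_motion(self, base, rng):
        rec = make_base_record(base)
        f0 = compute_base_frame(rec)
        for _ in range(20):
            R, t = random_rigid_motion(rng)
            f1 = compute_base_frame(moved(rec, R, t))
            np.testing.assert_allclose(f1.normal, R @ f0.normal, atol=1e-9)
            np.testing.assert_allclose(f1.center, R @ f0.center + t, atol=1e-9)

    def test_frame_matches_independent_oracle(self, rng):
        for base in STANDARD_BASES:
            rec = make_base_record(base)
            R, t = random_rigid_motion(rng)
            rec = moved(rec, R, t)
            frame = compute_base_frame(rec)
            c, n = frame_oracle(rec)
            np.testing.assert_allclose(frame.center, c, atol=1e-9)
            np.testing.assert_allclose(frame.normal, n, atol=1e-9)

    def test_missing_ring_atom_raises(self):
        rec = make_base_record("G")
        del rec.atoms["N7"]
        with pytest.raises(FrameError):
            compute_base_frame(rec)

    def test_projection_reconstruction_identity(self, rng):
        frame = compute_base_frame(make_base_record("A"))
        for _ in range(100):
            p = rng.normal(scale=8.0, size=3)
            x, y, z = frame.project(p)
            np.testing.assert_allclose(frame.unproject(x, y, z), p, atol=1e-9)

    def test_axial_points_project_to_origin(self):
        frame = compute_base_frame(make_base_record("U"))
        x, y, z = frame.project(frame.center + 3.0 * frame.normal)
        assert abs(x) < 1e-12 and abs(y) < 1e-12 and z == pytest.approx(3.0)
        x, y, z = frame.project(frame.center - 3.0 * frame.normal)
        assert z == pytest.approx(-3.0)


class TestEllipse:
    def test_exact_circle(self):
        th = np.linspace(0, 2 * np.pi, 7)[:-1]
        e = fit_ring_ellipse(np.c_[1.4 * np.cos(th), 1.4 * np.sin(th)])
        assert e.semi_axes[0] == pytest.approx(1.4, abs=1e-9)
        assert e.semi_axes[1] == pytest.approx(1.4, abs=1e-9)

    @pytest.mark.parametrize("a,b,phi", [(1.5, 1.3, 0.0), (1.5, 1.3, 0.7), (2.0, 0.9, -1.1)])
    def test_recovers_synthesised_ellipse(self, a, b, phi):
        th = np.linspace(0.3, 2 * np.pi, 7)[:-1]
        x = a * np.cos(th)
        y = b * np.sin(th)
        c, s = np.cos(phi), np.sin(phi)
        pts = np.c_[c * x - s * y + 0.4, s * x + c * y - 1.2]
        e = fit_ring_ellipse(pts)
        assert e.semi_axes[0] == pytest.approx(a, abs=1e-6)
        assert e.semi_axes[1] == pytest.approx(b, abs=1e-6)
        np.testing.assert_allclose(e.center_2d, [0.4, -1.2], atol=1e-6)

    @pytest.mark.parametrize("base", STANDARD_BASES)
    def test_ring_eccentricity_small(self, base):
        frame = compute_base_frame(make_base_record(base))
        for e in frame.rings:
            assert e.semi_axes[0] / e.semi_axes[1] < 1.3

    def test_collinear_points_rejected(self):
        pts = np.c_[np.arange(5.0), 2.0 * np.arange(5.0)]
        with pytest.raises(ValueError):
            fit_ring_ellipse(pts)

    @pytest.mark.parametrize("base", STANDARD_BASES)
    def test_expanded_ellipse_clears_ring_corners_by_margin(self, base):
        frame = compute_base_frame(make_base_record(base))
        for poly, exp in zip(frame.ring_polygons, frame.expanded_rings):
            d = poly - exp.center_2d
            r = np.linalg.norm(d, axis=1)
            th = np.arctan2(d[:, 1], d[:, 0])
            from zmotif.base_frames import _boundary_radius

            margins = [_boundary_radius(exp, t) - ri for t, ri in zip(th, r)]
            # the boundary passes exactly 0.3 A beyond the most outlying
            # corner and clears every other corner
            i_max = int(np.argmax(r))
            assert margins[i_max] == pytest.approx(0.3, abs=1e-9)
            assert min(margins) > 0.0


class TestLocateProjection:
    @pytest.mark.parametrize("base", STANDARD_BASES)
    def test_ring_centroid_inside_and_far_point_outside(self, base):
        frame = compute_base_frame(make_base_record(base))
        for poly in frame.ring_polygons:
            assert locate_projection(frame, poly.mean(axis=0)).kind == "inside_ring"
        assert locate_projection(frame, (10.0, 10.0)).kind == "outside"

    @pytest.mark.parametrize("base", STANDARD_BASES)
    def test_matches_polygon_and_conic_oracle(self, base, rng):
        """10^4 random in-plane points classify identically to the
        shapely point-in-polygon + conic-inequality oracle."""
        frame = compute_base_frame(make_base_record(base))
        pts = rng.uniform(-4.0, 4.0, size=(10_000, 2))
        for xy in pts:
            got = locate_projection(frame, xy)
            kind, ids = locate_oracle(frame, xy)
            assert got.kind == kind
            assert tuple(got.ring_ids) == ids

    def test_membership_nesting(self, rng):
        """inside_ring implies inside the expanded ellipse of that ring."""
        frame = compute_base_frame(make_base_record("G"))
        pts = rng.uniform(-3.0, 3.0, size=(2000, 2))
        for xy in pts:
            loc = locate_projection(frame, xy)
            if loc.kind == "inside_ring":
                assert any(frame.expanded_rings[i].contains(xy) for i in loc.ring_ids)
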