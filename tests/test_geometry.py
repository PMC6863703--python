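"""Rigid transforms, hydrogen-bond evaluation, grid snapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbnetforge.errors import GeometryError, ValidationError
from hbnetforge.geometry import (
    HBondParams,
    RigidTransform,
    angle_deg,
    apply_transform,
    dihedral_deg,
    hbond_eval,
    local_frame,
    place_atom,
    rotation_about_axis,
    snap_to_grid,
    superpose_frames,
)


def rand_transform(seed):
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    return RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                          rng.normal(size=3) * 5)


class TestRigidTransform:
    def test_identity_leaves_points_unchanged(self):
        pts = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        out = apply_transform(RigidTransform.identity(), pts)
        np.testing.assert_allclose(out, pts)

    def test_pure_translation(self):
        t = RigidTransform(np.eye(3), [1.0, 0.0, 0.0])
        np.testing.assert_allclose(t.apply([0.0, 0.0, 0.0]), [1.0, 0.0, 0.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_compose_with_inverse_is_identity(self, seed):
        t = rand_transform(seed)
        ti = t.compose(t.inverse())
        np.testing.assert_allclose(ti.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(ti.translation, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", list(range(5)))
    def test_rigid_motion_preserves_distances(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3)) * 3
        out = rand_transform(seed).apply(pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=2)
        np.testing.assert_allclose(d_in, d_out, atol=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))
        with pytest.raises(ValidationError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestSuperposeFrames:
    TRI = np.array([[0.0, 0, 0], [1.5, 0, 0], [0.8, 1.2, 0]])

    def test_identical_triples_give_identity(self):
        t = superpose_frames(self.TRI, self.TRI)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)

    def test_rotation_recovered(self):
        R = rotation_about_axis([0, 0, 1.0], 90.0)
        dst = self.TRI @ R.T
        t = superpose_frames(self.TRI, dst)
        np.testing.assert_allclose(t.apply(self.TRI), dst, atol=1e-6)
        np.testing.assert_allclose(t.rotation, R, atol=1e-6)

    def test_collinear_points_rejected(self):
        bad = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(GeometryError):
            superpose_frames(bad, bad)

    def test_non_congruent_triangles_rejected(self):
        dst = self.TRI.copy()
        dst[2, 1] += 0.3
        with pytest.raises(GeometryError):
            superpose_frames(self.TRI, dst)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_random_motion_recovered_exactly(self, seed):
        t = rand_transform(seed)
        dst = t.apply(self.TRI)
        rec = superpose_frames(self.TRI, dst)
        np.testing.assert_allclose(rec.apply(self.TRI), dst, atol=1e-6)


class TestPlaceAtom:
    @pytest.mark.parametrize("dist,ang,dih", [(1.5, 109.5, 60.0), (1.0, 120.0, -45.0),
                                              (2.8, 90.0, 180.0)])
    def test_internal_coordinates_reproduced(self, dist, ang, dih):
        a, b, c = np.zeros(3), np.array([1.5, 0, 0]), np.array([2.2, 1.3, 0])
        x = place_atom(a, b, c, dist, ang, dih)
        assert np.linalg.norm(x - c) == pytest.approx(dist, abs=1e-9)
        assert angle_deg(x, c, b) == pytest.approx(ang, abs=1e-8)
        assert dihedral_deg(x, c, b, a) == pytest.approx(dih, abs=1e-8)


class TestHBondEval:
    def geom(self, d=2.8, theta=180.0, psi=120.0):
        """Donor at origin, acceptor along +x; explicit analytic geometry."""
        D = np.zeros(3)
        A = np.array([d, 0.0, 0.0])
        # hydrogen on the D-A axis for theta=180, else tilted in xy-plane
        if theta == 180.0:
            H = np.array([1.0, 0.0, 0.0])
        else:
            # place H so that angle D-H-A = theta
            gamma = np.degrees(np.arcsin(np.sin(np.radians(theta)) / d))
            alpha = 180.0 - theta - gamma
            H = np.array([np.cos(np.radians(alpha)), np.sin(np.radians(alpha)), 0.0])
        # psi is the angle base-A...H; A->H points along -x here
        u = np.radians(180.0 - psi)
        base = A + 1.4 * np.array([np.cos(u), np.sin(u), 0.0])
        return D, H, A, base

    def test_ideal_geometry_scores_minimum(self):
        D, H, A, base = self.geom()
        ok, score = hbond_eval(D, H, A, base)
        assert ok and score == pytest.approx(-1.0)

    def test_distance_outside_window_fails(self):
        D, H, A, base = self.geom(d=3.5)
        ok, score = hbond_eval(D, H, A, base)
        assert not ok and score == 0.0

    def test_donor_angle_below_minimum_fails(self):
        D = np.zeros(3)
        H = np.array([1.0, 0.0, 0.0])
        A = H + 1.9 * np.array([np.cos(np.radians(90)), np.sin(np.radians(90)), 0])
        base = A + np.array([0.0, 1.4, 0.0])
        ok, _ = hbond_eval(D, H, A, base)  # theta = 90 < 120
        assert not ok

    def test_acceptor_angle_below_minimum_fails(self):
        D, H, A, _ = self.geom()
        base = A + np.array([-1.4, 0.0, 0.0])  # psi ~ 0: base points at H
        ok, _ = hbond_eval(D, H, A, base)
        assert not ok

    def test_best_base_atom_is_used(self):
        D, H, A, good = self.geom()
        bad = A + np.array([-1.4, 0.0, 0.0])
        ok1, s1 = hbond_eval(D, H, A, np.array([good, bad]))
        ok2, s2 = hbond_eval(D, H, A, np.array([bad, good]))
        assert ok1 and ok2 and s1 == s2

    def test_overlapping_atoms_raise(self):
        with pytest.raises(GeometryError):
            hbond_eval([0, 0, 0], [1, 0, 0], [0.2, 0, 0], [[1, 1, 0]])

    def test_score_vanishes_on_window_boundary(self):
        for d in (2.6, 3.2):
            D, H, A, base = self.geom(d=d)
            ok, score = hbond_eval(D, H, A, base)
            assert ok and score == pytest.approx(0.0, abs=1e-12)

    def test_score_continuous_in_distance(self):
        scores = []
        for d in np.linspace(2.6, 3.2, 61):
            D, H, A, base = self.geom(d=float(d))
            _, s = hbond_eval(D, H, A, base)
            scores.append(s)
        diffs = np.abs(np.diff(scores))
        # steepest ramp slope is 1/(ideal_d - d_min) = 5 per A; 0.01 A steps
        assert diffs.max() <= 0.051

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            HBondParams(d_min=3.0, d_max=2.8)


class TestGrid:
    @pytest.mark.parametrize(
        "point,g,expected",
        [
            ((0, 0, 0), 0.2, (0, 0, 0)),
            ((0.31, -0.11, 0.50), 0.2, (2, -1, 3)),  # half away from zero
            ((-0.5, 0.5, 0.0), 1.0, (-1, 1, 0)),
        ],
    )
    def test_snap_examples(self, point, g, expected):
        assert snap_to_grid(np.array(point, dtype=float), g) == expected

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            snap_to_grid([0.0, 0, 0], 0.0)

    @given(
        st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
        st.floats(0.05, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_snap_error_bounded_by_half_spacing(self, p, g):
        key = snap_to_grid(np.array(p), g)
        back = np.array(key) * g
        assert np.all(np.abs(back - np.array(p)) <= g / 2 + 1e-9)

    def test_nearby_points_share_a_key(self):
        g = 0.2
        node = np.array([3, -2, 7]) * g
        for delta in ([0.04, -0.03, 0.02], [-0.05, 0.05, -0.04]):
            assert snap_to_grid(node + delta, g) == (3, -2, 7)


class TestLocalFrame:
    def test_frame_canonicalizes_rigid_motions(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(5, 3)) * 4
        f = local_frame(pts)
        local = f.apply(pts)
        t = rand_transform(11)
        local2 = local_frame(t.apply(pts)).apply(t.apply(pts))
        np.testing.assert_allclose(local, local2, atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(GeometryError):
            local_frame(pts)
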