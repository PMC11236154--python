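"""Elliptic Fourier decomposition, normalization and reconstruction."""

import numpy as np
import pytest

import spermshape as ss
from spermshape import FormatError, GeometryError, ParameterError

from conftest import circle_points, ellipse_points, random_blob, symmetric_hausdorff


def quadrature_efd(x, y, s, T, n):
    """Independent Fourier oracle: trapezoid quadrature over dense samples
    of a curve given at arc-length positions s (periodic, period T)."""
    w = 2.0 * np.pi * n * s / T
    a = 2.0 / T * np.trapezoid(x * np.cos(w), s)
    b = 2.0 / T * np.trapezoid(x * np.sin(w), s)
    c = 2.0 / T * np.trapezoid(y * np.cos(w), s)
    d = 2.0 / T * np.trapezoid(y * np.sin(w), s)
    return np.array([a, b, c, d])


class TestDecompose:
    def test_unit_circle_first_harmonic(self):
        c = ss.decompose(circle_points(512), H=8)
        assert np.allclose(c.coeffs[0], [1, 0, 0, 1], atol=1e-3)
        assert np.abs(c.coeffs[1:]).max() < 1e-3
        assert abs(c.A0) < 1e-9 and abs(c.C0) < 1e-9
        assert c.T == pytest.approx(2 * np.pi, rel=1e-3)

    def test_ellipse_matches_quadrature_oracle(self):
        # Arc-length parameterization of a 2:1 ellipse: compare against a
        # dense trapezoid-quadrature Fourier oracle, harmonic by harmonic.
        pts = ellipse_points(2.0, 1.0, 8192)
        c = ss.decompose(pts, H=5)
        closed = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        s_nodes = np.concatenate([[0.0], np.cumsum(seg)])
        for n in range(1, 6):
            oracle = quadrature_efd(closed[:, 0], closed[:, 1], s_nodes, s_nodes[-1], n)
            assert np.allclose(c.coeffs[n - 1], oracle, atol=1e-6)
        # loosely the angle-parameterized values: a1 ~ 2, d1 ~ 1
        assert c.coeffs[0][0] == pytest.approx(2.0, rel=0.1)
        assert abs(c.coeffs[0][3]) == pytest.approx(1.0, rel=0.1)
        assert abs(c.coeffs[0][1]) < 1e-6 and abs(c.coeffs[0][2]) < 1e-6

    @pytest.mark.parametrize("H,length", [(20, 80), (1, 4), (7, 28)])
    def test_flat_vector_length(self, H, length, default_head):
        assert ss.flatten(ss.decompose(default_head, H=H)).size == length

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            ss.decompose(circle_points(64), H=0)
        with pytest.raises(GeometryError):
            ss.decompose(np.zeros((5, 2)), H=2)


class TestNormalize:
    def test_circle_canonical(self):
        n = ss.normalize(ss.decompose(circle_points(512), H=6))
        assert np.allclose(n.coeffs[0], [1, 0, 0, 1], atol=1e-6)
        assert np.abs(n.coeffs[1:]).max() < 1e-6

    def test_invariants_hold(self, default_head):
        n = ss.normalize(ss.decompose(default_head, H=20))
        assert abs(n.coeffs[0, 1]) < 1e-9   # b1
        assert abs(n.coeffs[0, 2]) < 1e-9   # c1
        assert n.coeffs[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_similarity_and_start_invariance(self, rng):
        # 50 random simple contours x random rotation/scale/start/translation
        for _ in range(50):
            blob = random_blob(rng)
            v0 = ss.flatten(ss.normalize(ss.decompose(blob, H=12)))
            ang = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            moved = (
                np.roll(blob, rng.integers(len(blob)), axis=0) @ R.T
                * rng.uniform(0.3, 3.0)
                + rng.uniform(-100, 100, 2)
            )
            v1 = ss.flatten(ss.normalize(ss.decompose(moved, H=12)))
            assert np.abs(v1 - v0).max() < 1e-6

    def test_specific_transform_case(self, default_head):
        pts = default_head.points
        v0 = ss.flatten(ss.normalize(ss.decompose(pts, H=20)))
        ang = np.deg2rad(37.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = np.roll(pts, 41, axis=0) @ R.T * 3.0 + np.array([120.0, -55.0])
        v1 = ss.flatten(ss.normalize(ss.decompose(moved, H=20)))
        assert np.abs(v1 - v0).max() < 1e-6

    def test_mirror_chirality(self, default_head):
        pts = default_head.points
        mirrored = np.column_stack([-pts[:, 0], pts[:, 1]])[::-1]  # stay CCW
        v = ss.flatten(ss.normalize(ss.decompose(pts, H=12)))
        vm = ss.flatten(ss.normalize(ss.decompose(mirrored, H=12)))
        # chirality is preserved by default: the codes differ...
        assert np.abs(v - vm).max() > 1e-3
        # ...but only by sign flips of individual entries
        assert np.allclose(np.abs(v), np.abs(vm), atol=1e-9)
        # canonical chirality maps both to the same vector
        vc = ss.flatten(ss.normalize(ss.decompose(pts, H=12), canonical_chirality=True))
        vmc = ss.flatten(ss.normalize(ss.decompose(mirrored, H=12), canonical_chirality=True))
        assert np.abs(vc - vmc).max() < 1e-9

    def test_degenerate_first_harmonic(self):
        bad = ss.EFDCoefficients(np.zeros((3, 4)), 0.0, 0.0, 1.0)
        with pytest.raises(GeometryError):
            ss.normalize(bad)

    def test_flags_off_keeps_scale(self, default_head):
        raw = ss.decompose(default_head, H=8)
        unscaled = ss.normalize(raw, do_scale=False)
        scaled = ss.normalize(raw)
        assert unscaled.scale == 1.0
        # the unscaled code is the scaled code times the removed size factor
        assert np.allclose(unscaled.coeffs, scaled.coeffs * scaled.scale, atol=1e-9)


class TestReconstruct:
    def test_pure_first_harmonic_is_unit_circle(self):
        coeffs = ss.unflatten([1.0, 0.0, 0.0, 1.0], H=1)
        pts = ss.reconstruct(coeffs, 64).points
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-9)

    def test_roundtrip_hausdorff(self, default_head):
        rec = ss.reconstruct(ss.decompose(default_head, H=127), 512)
        assert symmetric_hausdorff(default_head.points, rec.points) < 0.5

    def test_error_non_increasing_in_harmonics(self, default_head):
        errors = []
        for H in [1, 2, 5, 10, 20, 50, 127]:
            rec = ss.reconstruct(ss.decompose(default_head, H=H), 512)
            errors.append(symmetric_hausdorff(default_head.points, rec.points))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errors, errors[1:]))

    def test_first_harmonic_is_best_fit_ellipse(self, default_head):
        n = ss.normalize(ss.decompose(default_head, H=1), do_scale=False)
        rec = ss.reconstruct(n, 2048)
        a1, d1 = n.coeffs[0, 0], n.coeffs[0, 3]
        assert rec.area <= np.pi * a1 * abs(d1) * 1.01

    def test_min_points(self, default_head):
        with pytest.raises(ParameterError):
            ss.reconstruct(ss.decompose(default_head, H=4), n_points=4)


class TestFlatten:
    def test_roundtrip_bijection(self, default_head):
        n = ss.normalize(ss.decompose(default_head, H=20))
        v = ss.flatten(n)
        assert v.size == 80
        back = ss.unflatten(v, H=20)
        assert np.array_equal(back.coeffs, n.coeffs)

    def test_length_mismatch(self):
        with pytest.raises(FormatError):
            ss.unflatten(np.zeros(10), H=20)


class TestProperties:
    def test_parseval_scaling(self, default_head, rng):
        """Pre-normalization coefficient energy scales with the square of
        an applied scale factor."""
        base = ss.decompose(default_head, H=16).coeffs
        for s in rng.uniform(0.2, 5.0, 5):
            scaled = ss.decompose(default_head.points * s, H=16).coeffs
            assert np.sum(scaled**2) == pytest.approx(s**2 * np.sum(base**2), rel=1e-9)
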