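"""Rotation-invariant statistics: cross-spectra, moments, R^2, Q,
orientation extraction and the squared-representation expansion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sigtt
from sigtt.basis import BasisConvention, evaluate_basis, quadrature_grid, rotate_expansion
from sigtt.invariants import (
    cross_spectrum,
    ensemble_q,
    expand_squared,
    main_orientation,
    moments,
    r_squared,
    relative_anisotropy,
    tukey_summary,
)

from conftest import random_rotation, random_unit_vectors

SQRT4PI = np.sqrt(4 * np.pi)


def _dense_average(coeffs, fn=lambda f: f):
    """Sphere-surface average of fn(f) by exact quadrature."""
    conv = BasisConvention({1: 0, 6: 2, 15: 4, 28: 6, 91: 12}[len(coeffs)])
    dirs, wts = quadrature_grid(2 * conv.ell_max)
    f = evaluate_basis(dirs, conv) @ coeffs
    return float((wts * fn(f)).sum() / (4 * np.pi))


class TestCrossSpectrum:
    def test_constant_function(self):
        c = np.zeros(28)
        c[0] = SQRT4PI  # the constant function 1
        S = cross_spectrum(c, c)
        assert S[0] == pytest.approx(1.0)
        assert np.abs(S[1:]).max() == 0.0

    def test_sum_equals_surface_average_of_product(self, rng):
        g, h = rng.normal(size=(2, 28))
        S = cross_spectrum(g, h)
        conv = BasisConvention(6)
        dirs, wts = quadrature_grid(6)
        B = evaluate_basis(dirs, conv)
        oracle = float((wts * (B @ g) * (B @ h)).sum() / (4 * np.pi))
        assert S.sum() == pytest.approx(oracle, abs=1e-8)

    def test_rotation_invariance(self, rng):
        g, h = rng.normal(size=(2, 28))
        R = random_rotation(rng)
        S0 = cross_spectrum(g, h)
        S1 = cross_spectrum(rotate_expansion(g, R), rotate_expansion(h, R))
        assert np.abs(S0 - S1).max() < 1e-10

    def test_convention_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_spectrum(rng.normal(size=28), rng.normal(size=15))


class TestMoments:
    def test_constant_function(self):
        c = np.zeros(28)
        c[0] = SQRT4PI
        mean, var, _ = moments(c)
        assert mean == pytest.approx(1.0)
        assert var == pytest.approx(0.0, abs=1e-15)

    def test_cov_of_self_is_var(self, rng):
        g = rng.normal(size=28)
        _, var, cov = moments(g, g)
        assert cov == pytest.approx(var)

    def test_var_matches_dense_quadrature(self, rng):
        g = rng.normal(size=28)
        mean, var, _ = moments(g)
        mean_o = _dense_average(g)
        var_o = _dense_average(g, lambda f: f * f) - mean_o**2
        assert mean == pytest.approx(mean_o, abs=1e-10)
        assert var == pytest.approx(var_o, abs=1e-8)


class TestRelativeAnisotropy:
    def test_isotropic_is_zero(self):
        c = np.zeros(15)
        c[0] = 3.0
        assert relative_anisotropy(c) == pytest.approx(0.0)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None, max_examples=20)
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(5)
        g = rng.normal(size=28)
        g[0] = abs(g[0]) + 5.0  # positive mean
        assert relative_anisotropy(k * g) == pytest.approx(
            relative_anisotropy(g), rel=1e-10
        )

    def test_matches_dense_sampling(self, rng):
        g = rng.normal(size=28)
        g[0] = abs(g[0]) + 5.0
        mean_o = _dense_average(g)
        var_o = _dense_average(g, lambda f: f * f) - mean_o**2
        assert relative_anisotropy(g) == pytest.approx(
            np.sqrt(var_o) / mean_o, abs=1e-4
        )

    def test_nonpositive_mean_flagged(self):
        c = np.zeros(6)
        c[0] = -1.0
        assert np.isnan(relative_anisotropy(c))


class TestRSquared:
    def test_self_correlation_is_one(self, rng):
        g = rng.normal(size=28)
        assert r_squared(g, g) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        # identical up to offset and scaling: still R^2 = 1
        g = rng.normal(size=28)
        h = 5.0 * g
        h[0] += 2.0 * SQRT4PI  # add the constant 2
        assert r_squared(g, h) == pytest.approx(1.0)

    def test_common_rotation_invariance(self, rng):
        g, h = rng.normal(size=(2, 28))
        R = random_rotation(rng)
        assert r_squared(
            rotate_expansion(g, R), rotate_expansion(h, R)
        ) == pytest.approx(r_squared(g, h), abs=1e-8)

    def test_matches_pearson_of_dense_samples(self, rng):
        g, h = rng.normal(size=(2, 28))
        conv = BasisConvention(6)
        dirs, wts = quadrature_grid(8)
        B = evaluate_basis(dirs, conv)
        fg, fh = B @ g, B @ h
        w = wts / wts.sum()
        mg, mh = (w * fg).sum(), (w * fh).sum()
        cov = (w * (fg - mg) * (fh - mh)).sum()
        corr2 = cov**2 / (
            (w * (fg - mg) ** 2).sum() * (w * (fh - mh) ** 2).sum()
        )
        assert r_squared(g, h) == pytest.approx(corr2, abs=1e-6)

    def test_zero_variance_undefined(self):
        iso = np.zeros(28)
        iso[0] = 1.0
        assert np.isnan(r_squared(iso, iso))


class TestEnsembleQ:
    def test_identical_members_give_one(self, rng):
        c = rng.normal(size=(2, 2, 2, 28))
        q = ensemble_q([c] * 10)
        assert np.allclose(q, 1.0)

    def test_single_member_gives_one(self, rng):
        c = rng.normal(size=(1, 1, 1, 15))
        assert ensemble_q([c])[0, 0, 0] == pytest.approx(1.0)

    def test_two_member_rotated_oracle(self, rng):
        # two equal-power l=2 maps rotated 90 degrees apart; compare
        # against brute-force evaluation of the defining ratio
        conv = BasisConvention(2)
        z = np.array([0.0, 0.0, 1.0])
        g1 = sigtt.zonal_delta_coefficients(z, np.array([0.0, 1.0]), conv)
        Rx = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        g2 = rotate_expansion(g1, Rx)
        q = ensemble_q([g1[None, None, None], g2[None, None, None]])[0, 0, 0]
        # oracle: direct coefficient arithmetic of the definition
        mean_fn = (g1 + g2) / 2
        var_mean = cross_spectrum(mean_fn, mean_fn)[1:].sum()
        mean_var = (
            cross_spectrum(g1, g1)[1:].sum() + cross_spectrum(g2, g2)[1:].sum()
        ) / 2
        assert q == pytest.approx(var_mean / mean_var)
        assert 0.0 <= q < 1.0

    def test_all_isotropic_undefined(self):
        iso = np.zeros((1, 1, 1, 6))
        iso[..., 0] = 1.0
        assert np.isnan(ensemble_q([iso, iso])[0, 0, 0])

    def test_bounded_on_random_ensembles(self, rng):
        vols = [rng.normal(size=(3, 3, 3, 15)) for _ in range(5)]
        q = ensemble_q(vols)
        assert np.nanmin(q) >= 0.0 and np.nanmax(q) <= 1.0 + 1e-12


class TestMainOrientation:
    def test_zonal_about_z(self):
        conv = BasisConvention(6)
        c = sigtt.zonal_delta_coefficients([0, 0, 1.0], np.ones(4), conv)
        o = main_orientation(c)
        assert np.allclose(np.abs(o.vector), [0, 0, 1], atol=1e-10)
        assert o.vector[2] > 0  # hemisphere convention

    def test_rotation_equivariance(self, rng):
        conv = BasisConvention(6)
        c = sigtt.zonal_delta_coefficients([0, 0, 1.0], np.ones(4), conv)
        for _ in range(5):
            R = random_rotation(rng)
            o = main_orientation(rotate_expansion(c, R))
            expected = R @ np.array([0, 0, 1.0])
            dot = abs(o.vector @ expected)
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_pure_l2_matches_tensor_eigendecomposition(self, rng):
        # build a function from a known symmetric traceless tensor and
        # recover that tensor's distinct eigenvector
        conv = BasisConvention(2)
        n = random_unit_vectors(rng, 1)[0]
        # zonal l=2 about n: tensor is n n^T - I/3 up to positive scale
        c = sigtt.zonal_delta_coefficients(n, np.array([0.0, 1.0]), conv)
        T = np.outer(n, n) - np.eye(3) / 3
        evals, evecs = np.linalg.eigh(T)
        o = main_orientation(c)
        assert abs(o.vector @ evecs[:, 2]) == pytest.approx(1.0, abs=1e-8)

    def test_zero_l2_rejected(self):
        c = np.zeros(6)
        c[0] = 1.0
        with pytest.raises(ValueError):
            main_orientation(c)


class TestExpandSquared:
    def test_square_of_constant(self):
        c = np.zeros(28)
        c[0] = 2.0 * SQRT4PI  # constant 2
        sq = expand_squared(c, 12)
        mean, var, _ = moments(sq)
        assert mean == pytest.approx(4.0)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_variance_against_dense_quadrature(self, rng):
        # the headline accuracy check: squared ell_max=6 functions
        # expanded to ell_max=12; variance relative error well below 0.1%
        conv = BasisConvention(6)
        dirs, wts = quadrature_grid(12)
        B = evaluate_basis(dirs, conv)
        worst = 0.0
        for _ in range(25):
            c = rng.normal(size=28)
            sq = expand_squared(c, 12)
            var = moments(sq)[1]
            f2 = (B @ c) ** 2
            mean_o = (wts * f2).sum() / (4 * np.pi)
            var_o = (wts * f2 * f2).sum() / (4 * np.pi) - mean_o**2
            worst = max(worst, abs(var - var_o) / var_o)
        assert worst < 1e-3  # 0.1 %

    def test_single_y20_square_against_quadrature_oracle(self):
        # the square of Y_2^0 is a known zonal l<=4 polynomial; check
        # every expanded coefficient against brute-force projection on
        # an independent (trapezoid lat-long) grid
        c = np.zeros(6)
        c[3] = 1.0  # Y_2^0 (ordering: (0,0), (2,-2), (2,-1), (2,0), ...)
        sq = expand_squared(c, 4)
        theta = np.linspace(0, np.pi, 800)
        phi = np.linspace(0, 2 * np.pi, 800, endpoint=False)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        dirs = np.stack(
            [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], -1
        ).reshape(-1, 3)
        conv2, conv4 = BasisConvention(2), BasisConvention(4)
        f2 = (evaluate_basis(dirs, conv2) @ c) ** 2
        w = (np.sin(tt) * (theta[1] - theta[0]) * (phi[1] - phi[0])).ravel()
        oracle = (f2 * w) @ evaluate_basis(dirs, conv4)
        assert np.abs(sq - oracle).max() < 1e-5
        # only zonal (m=0) terms survive
        nonzero = [lm for lm, v in zip(conv4.orders, sq) if abs(v) > 1e-10]
        assert all(m == 0 for _, m in nonzero)

    def test_insufficient_output_band_rejected(self, rng):
        with pytest.raises(ValueError):
            expand_squared(rng.normal(size=28), 10)


def test_tukey_summary_whiskers():
    # whiskers at the data extremes inside Q1/Q3 -/+ 1.25 IQR
    v = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8, 100.0])
    s = tukey_summary(v)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    assert s["lo"] == 0.0
    assert s["hi"] == 8.0  # 100 lies beyond Q3 + 1.25 IQR
    assert s["hi"] <= q3 + 1.25 * iqr


def test_invariant_maps_rotation_invariance(rng):
    # every voxel statistic unchanged under a common rotation of the field
    from sigtt.invariants import compute_invariant_maps

    values = rng.normal(size=(2, 2, 2, 15))
    ref = rng.normal(size=(2, 2, 2, 15))
    R = random_rotation(rng)
    rot = rotate_expansion(values, R)
    rot_ref = rotate_expansion(ref, R)
    m0 = compute_invariant_maps(values, reference=ref, with_orientation=False)
    m1 = compute_invariant_maps(rot, reference=rot_ref, with_orientation=False)
    for name in ("mean", "power", "rel_aniso", "r2"):
        a, b = getattr(m0, name), getattr(m1, name)
        assert np.allclose(a, b, atol=1e-8, equal_nan=True)
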