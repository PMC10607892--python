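"""Conventional inverse vs Wiener (linear MMSE) separation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirpulse import (
    ConfigurationError,
    DensitySeries,
    InputError,
    SystemMatrix,
    build_noise_autocorrelation,
    build_pigment_autocorrelation,
    conventional_separate,
    default_forward_matrix,
    wiener_matrix,
    wiener_separate,
)
from nirpulse.estimators import AutocorrelationMatrix

from .conftest import random_invertible_F


def matched_ensemble(rng, F, hb_range, shade, sigma, n):
    """Draw (r, v) pairs from the model the Wiener estimator assumes."""
    h = rng.uniform(hb_range[0], hb_range[1], size=n)
    r = np.column_stack([h, np.full(n, shade)])
    v = r @ F.entries.T + rng.normal(0.0, sigma, size=(n, 2))
    return r, v


def ensemble_mse(M, r, v):
    e = v @ M.T - r
    return float(np.mean(np.sum(e * e, axis=1)))


class TestConventionalSeparate:
    def test_identity_passthrough(self):
        v = DensitySeries(np.random.default_rng(0).normal(size=(10, 2)), 66.5)
        r = conventional_separate(SystemMatrix(np.eye(2)), v)
        np.testing.assert_allclose(r.vectors, v.vectors)
        assert r.method_tag == "conventional"

    def test_zero_maps_to_zero(self):
        v = DensitySeries(np.zeros((5, 2)), 66.5)
        r = conventional_separate(default_forward_matrix(), v)
        np.testing.assert_array_equal(r.vectors, 0.0)

    def test_hand_inverse(self):
        F = SystemMatrix(np.array([[2.0, 0.0], [0.0, 1.0]]))
        v = DensitySeries(np.array([[2.0, 3.0]]), 66.5)
        r = conventional_separate(F, v)
        np.testing.assert_allclose(r.vectors, [[1.0, 3.0]])

    def test_singular_matrix_rejected(self):
        F = SystemMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
        v = DensitySeries(np.zeros((2, 2)), 66.5)
        with pytest.raises(ConfigurationError):
            conventional_separate(F, v)


class TestPigmentAutocorrelation:
    def test_degenerate_range_is_exact_rank_one_moment(self):
        h, s = 0.7, 0.4
        R = build_pigment_autocorrelation((h, h), s, n_samples=10)
        np.testing.assert_allclose(
            R.entries, [[h * h, h * s], [h * s, s * s]], rtol=1e-14
        )
        assert R.provenance == "analytic"

    def test_uniform_second_moment_converges_to_third(self):
        # E[h^2] = 1/3 for h ~ U(0, 1)
        R = build_pigment_autocorrelation((0.0, 1.0), 0.0, n_samples=1_000_000, seed=5)
        np.testing.assert_allclose(R.entries[0, 0], 1.0 / 3.0, rtol=0.01)
        assert R.entries[1, 1] == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            build_pigment_autocorrelation((0.4, 0.2), 0.5, 10)
        with pytest.raises(InputError):
            build_pigment_autocorrelation((0.2, 0.4), 0.5, 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        lo=st.floats(-1, 1),
        width=st.floats(0, 1),
        shade=st.floats(-1, 1),
        seed=st.integers(0, 1000),
    )
    def test_always_symmetric_psd(self, lo, width, shade, seed):
        R = build_pigment_autocorrelation(
            (lo, lo + width), shade, n_samples=500, seed=seed
        )
        np.testing.assert_allclose(R.entries, R.entries.T)
        assert np.linalg.eigvalsh(R.entries).min() >= -1e-12


class TestWienerMatrix:
    def test_zero_noise_reduces_to_inverse(self, F):
        Rrr = build_pigment_autocorrelation((0.2, 0.4), 0.5, 100_000, seed=1)
        Rnn = build_noise_autocorrelation(0.0)
        G = wiener_matrix(Rrr, F, Rnn).G
        np.testing.assert_allclose(G, np.linalg.inv(F.entries), rtol=1e-10)

    def test_scalar_analogue(self):
        one = AutocorrelationMatrix(np.eye(2), role="pigment")
        G = wiener_matrix(one, SystemMatrix(np.eye(2)), AutocorrelationMatrix(np.eye(2), role="noise")).G
        np.testing.assert_allclose(G, 0.5 * np.eye(2))

    def test_matches_numerical_mse_minimizer(self, F):
        """G agrees with a brute-force MSE minimizer on a simulated ensemble."""
        import scipy.optimize

        rng = np.random.default_rng(7)
        hb_range, shade, sigma = (0.25, 0.35), 0.5, 0.01
        r, v = matched_ensemble(rng, F, hb_range, shade, sigma, 50_000)
        Rrr = build_pigment_autocorrelation(hb_range, shade, 1_000_000, seed=2)
        Rnn = build_noise_autocorrelation(sigma)
        G = wiener_matrix(Rrr, F, Rnn).G

        res = scipy.optimize.minimize(
            lambda g: ensemble_mse(g.reshape(2, 2), r, v),
            np.linalg.inv(F.entries).ravel(),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 20_000},
        )
        G_opt = res.x.reshape(2, 2)
        assert ensemble_mse(G, r, v) <= ensemble_mse(G_opt, r, v) * (1 + 1e-3)

    def test_singular_inner_matrix_reported(self):
        zero = AutocorrelationMatrix(np.zeros((2, 2)), role="pigment")
        with pytest.raises(Exception, match="condition"):
            wiener_matrix(zero, SystemMatrix(np.eye(2)), AutocorrelationMatrix(np.zeros((2, 2)), role="noise"))


class TestWienerSeparate:
    def test_identity_estimator_passthrough(self, F):
        Rrr = build_pigment_autocorrelation((0.2, 0.4), 0.5, 10_000, seed=3)
        est = wiener_matrix(Rrr, SystemMatrix(np.eye(2)), build_noise_autocorrelation(0.0))
        v = DensitySeries(np.random.default_rng(1).normal(size=(20, 2)), 66.5)
        out = wiener_separate(est, v)
        np.testing.assert_allclose(out.vectors, v.vectors, rtol=1e-10)
        assert out.method_tag == "wiener"

    def test_zero_noise_equals_conventional(self, F):
        Rrr = build_pigment_autocorrelation((0.2, 0.4), 0.5, 10_000, seed=3)
        est = wiener_matrix(Rrr, F, build_noise_autocorrelation(0.0))
        v = DensitySeries(np.random.default_rng(2).normal(size=(50, 2)), 66.5)
        np.testing.assert_allclose(
            wiener_separate(est, v).vectors,
            conventional_separate(F, v).vectors,
            rtol=1e-8,
            atol=1e-12,
        )


class TestMseOptimality:
    def test_mse_dominance_over_conventional(self, F):
        """Ensemble MSE of the Wiener estimate never exceeds the inverse's."""
        rng = np.random.default_rng(11)
        hb_range, shade, sigma = (0.295, 0.305), 0.5, 0.0025
        r, v = matched_ensemble(rng, F, hb_range, shade, sigma, 10_000)
        Rrr = build_pigment_autocorrelation(hb_range, shade, 1_000_000, seed=4)
        G = wiener_matrix(Rrr, F, build_noise_autocorrelation(sigma)).G
        mse_w = ensemble_mse(G, r, v)
        mse_c = ensemble_mse(np.linalg.inv(F.entries), r, v)
        assert mse_w < mse_c  # strict: nonzero noise

    def test_local_optimality_under_perturbation(self, F):
        """No small perturbation of G reduces the ensemble MSE (beyond
        the finite-ensemble allowance ~ p/n of the minimum)."""
        rng = np.random.default_rng(12)
        hb_range, shade, sigma = (0.295, 0.305), 0.5, 0.0025
        r, v = matched_ensemble(rng, F, hb_range, shade, sigma, 10_000)
        Rrr = build_pigment_autocorrelation(hb_range, shade, 1_000_000, seed=5)
        G = wiener_matrix(Rrr, F, build_noise_autocorrelation(sigma)).G
        base = ensemble_mse(G, r, v)
        pert = np.random.default_rng(13)
        for _ in range(100):
            D = pert.normal(size=(2, 2))
            D *= 1e-2 * np.linalg.norm(G) / np.linalg.norm(D)
            assert ensemble_mse(G + D, r, v) >= base * (1 - 1e-3)

    def test_continuity_to_inverse_as_noise_vanishes(self, F):
        Rrr = build_pigment_autocorrelation((0.2, 0.4), 0.5, 200_000, seed=6)
        Finv = np.linalg.inv(F.entries)
        gaps = []
        for sigma in (1e-1, 1e-2, 1e-3, 1e-4, 1e-5):
            G = wiener_matrix(Rrr, F, build_noise_autocorrelation(sigma)).G
            gaps.append(np.linalg.norm(G - Finv))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        # gap decays ~ sigma^2 until limited by the sampled Rrr
        assert gaps[-1] < 1e-3 and gaps[-1] < 1e-4 * gaps[0]


def test_data_driven_form_agrees_with_model_form(F):
    """G from sampled cross/auto-correlations (the data-driven estimator)
    agrees with the model-based formula on a matched ensemble."""
    rng = np.random.default_rng(21)
    hb_range, shade, sigma = (0.295, 0.305), 0.5, 0.0025
    r, v = matched_ensemble(rng, F, hb_range, shade, sigma, 100_000)
    Rrv = r.T @ v / len(r)
    Rvv = v.T @ v / len(r)
    G_data = Rrv @ np.linalg.inv(Rvv)
    Rrr = build_pigment_autocorrelation(hb_range, shade, 1_000_000, seed=8)
    G = wiener_matrix(Rrr, F, build_noise_autocorrelation(sigma)).G
    assert np.linalg.norm(G_data - G) / np.linalg.norm(G) < 0.05
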