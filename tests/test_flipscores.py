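"""Tests for effective scores, flip ensembles and the standardized flip test."""

import numpy as np
import pytest

from flip2sss.flipscores import (
    ScoreDecomposition,
    effective_score,
    make_flips,
    mahalanobis_combine,
    standardized_flip_stats,
)
from flip2sss.glm_core import GlmSpec, fit_glm, log_likelihood

from conftest import random_glm_instance


def _profile_gradient(family, X, y, tested, eps=1e-5):
    """Central-difference gradient of the profile log-likelihood in the tested
    coefficient at 0 — the independent oracle for the effective score."""
    nuis = [j for j in range(X.shape[1]) if j != tested]

    def prof(bd):
        spec = GlmSpec(family, X[:, nuis], y, offset=bd * X[:, tested])
        fit = fit_glm(spec)
        full = np.zeros(X.shape[1])
        full[nuis] = fit.coefficients
        full[tested] = bd
        return log_likelihood(GlmSpec(family, X, y), full)

    return (prof(eps) - prof(-eps)) / (2 * eps)


def _null_decomposition(family, X, y, tested):
    nuis = [j for j in range(X.shape[1]) if j != tested]
    spec = GlmSpec(family, X[:, nuis], y)
    fit = fit_glm(spec)
    return effective_score(fit, spec, X, [tested])


class TestEffectiveScore:
    def test_gaussian_intercept_nuisance_closed_form(self, rng):
        n = 15
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        sd = _null_decomposition("gaussian", X, y, tested=1)
        assert sd.observed_score[0] == pytest.approx(np.sum(x * (y - y.mean())), rel=1e-10)
        assert sd.observed_score[0] == pytest.approx(
            _profile_gradient("gaussian", X, y, 1), rel=1e-6
        )

    def test_binomial_intercept_nuisance_matches_gradient(self, rng):
        n = 20
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.5).astype(float)
        X = np.column_stack([np.ones(n), x])
        sd = _null_decomposition("binomial", X, y, tested=1)
        # W-residualization of x against the intercept then times (y - ybar)
        assert sd.observed_score[0] == pytest.approx(
            _profile_gradient("binomial", X, y, 1), rel=1e-6
        )

    def test_contribution_sums_equal_observed_score(self, rng):
        for family in ("gaussian", "binomial", "poisson"):
            X, y = random_glm_instance(rng, family, n=18, q=3)
            sd = _null_decomposition(family, X, y, tested=2)
            np.testing.assert_allclose(sd.contributions.sum(axis=0), sd.observed_score)

    def test_invariant_to_nuisance_reparameterization(self, rng):
        # recombining the nuisance columns by any invertible matrix leaves the
        # effective-score contributions unchanged (same column space)
        X, y = random_glm_instance(rng, "binomial", n=25, q=4)
        base = _null_decomposition("binomial", X, y, tested=3)
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            while abs(np.linalg.det(A)) < 0.1:
                A = rng.normal(size=(3, 3))
            X2 = X.copy()
            X2[:, :3] = X[:, :3] @ A
            alt = _null_decomposition("binomial", X2, y, tested=3)
            np.testing.assert_allclose(alt.contributions, base.contributions, atol=1e-8)

    def test_orthogonal_tested_column_projection_unchanged(self, rng):
        n = 30
        nuis = np.ones((n, 1))
        xd = rng.normal(size=n)
        xd -= xd.mean()  # orthogonal to intercept under gaussian unit weights
        X = np.column_stack([nuis, xd])
        y = rng.normal(size=n)
        sd = _null_decomposition("gaussian", X, y, tested=1)
        np.testing.assert_allclose(sd.nuisance_projection[:, 0], xd, atol=1e-10)

    def test_aliased_tested_column_raises(self, rng):
        n = 12
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = rng.normal(size=n)
        spec = GlmSpec("gaussian", X[:, :2], y)
        fit = fit_glm(spec)
        with pytest.raises(ValueError, match="not identifiable"):
            effective_score(fit, spec, X, [2])


class TestMakeFlips:
    def test_exhaustive_small_n(self):
        fl = make_flips(3, 5000, seed=0)
        assert fl.mode == "exhaustive"
        assert fl.B == 8
        assert np.all(fl.flips[0] == 1)
        rows = {tuple(r) for r in fl.flips}
        assert len(rows) == 8

    def test_random_mode_reproducible(self):
        a = make_flips(50, 1000, seed=123)
        b = make_flips(50, 1000, seed=123)
        assert a.mode == "random"
        np.testing.assert_array_equal(a.flips, b.flips)
        assert np.all(a.flips[0] == 1)

    def test_different_seeds_differ(self):
        a = make_flips(50, 1000, seed=1)
        b = make_flips(50, 1000, seed=2)
        assert not np.array_equal(a.flips[1:], b.flips[1:])


class TestStandardizedFlipStats:
    def test_unit_contributions_enumeration(self):
        # nu = (1,1,1): raw flipped sums are {3, 1, 1, 1, -1, -1, -1, -3};
        # two-sided p for the observed 3 is 2/8
        sd = ScoreDecomposition(np.ones((3, 1)), np.array([0]), np.ones((3, 1)))
        fl = make_flips(3, 5000, seed=0)
        res = standardized_flip_stats(sd, fl)
        raw = np.sort(fl.flips @ np.ones(3))
        np.testing.assert_array_equal(raw, [-3, -1, -1, -1, 1, 1, 1, 3])
        assert res.p_two_sided == pytest.approx(2 / 8)
        assert res.p_greater == pytest.approx(1 / 8)

    def test_degenerate_zero_contributions(self):
        sd = ScoreDecomposition(np.zeros((6, 1)), np.array([0]), np.zeros((6, 1)))
        fl = make_flips(6, 100, seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            res = standardized_flip_stats(sd, fl)
        assert res.p_two_sided == 1.0
        assert res.degenerate

    def test_identity_flip_is_observed_studentized_score(self, rng):
        nu = rng.normal(size=12)
        sd = ScoreDecomposition(nu[:, None], np.array([0]), nu[:, None])
        fl = make_flips(12, 500, seed=3)
        res = standardized_flip_stats(sd, fl)
        s = nu.sum()
        expected = s / np.sqrt(np.sum(nu**2) - s**2 / 12)
        assert res.flipped_stats[0] == pytest.approx(res.observed)
        assert res.observed == pytest.approx(expected, rel=1e-12)

    def test_p_at_least_one_over_B(self, rng):
        nu = np.abs(rng.normal(size=8)) + 1  # strongly one-sided
        sd = ScoreDecomposition(nu[:, None], np.array([0]), nu[:, None])
        fl = make_flips(8, 5000, seed=0)  # exhaustive, B = 256
        res = standardized_flip_stats(sd, fl)
        assert res.p_greater >= 1 / fl.B
        assert res.p_two_sided >= 1 / fl.B

    def test_seed_invariance_under_exhaustive_enumeration(self, rng):
        nu = rng.normal(size=10)
        sd = ScoreDecomposition(nu[:, None], np.array([0]), nu[:, None])
        ps = [
            standardized_flip_stats(sd, make_flips(10, 2000, seed=s)).p_two_sided
            for s in (1, 7, 99)
        ]
        assert len(set(ps)) == 1


class TestMahalanobis:
    def test_k1_reduces_to_two_sided_scalar(self, rng):
        for _ in range(5):
            nu = rng.normal(size=20)
            sd = ScoreDecomposition(nu[:, None], np.array([0]), nu[:, None])
            fl = make_flips(20, 800, seed=11)
            scalar = standardized_flip_stats(sd, fl)
            combined = mahalanobis_combine(sd, fl)
            assert combined.p_two_sided == pytest.approx(scalar.p_two_sided)

    def test_rank_deficient_covariance_uses_pseudoinverse(self, rng):
        nu = rng.normal(size=15)
        contrib = np.column_stack([nu, 2 * nu])  # perfectly collinear columns
        sd = ScoreDecomposition(contrib, np.arange(2), contrib)
        fl = make_flips(15, 400, seed=5)
        with pytest.warns(UserWarning, match="rank"):
            res = mahalanobis_combine(sd, fl)
        assert 0 < res.p_two_sided <= 1

    def test_global_null_level_k2(self, rng):
        # independent halves combined: the global test keeps its level
        rej = 0
        reps = 1000
        for r in range(reps):
            contrib = rng.normal(size=(24, 2))
            sd = ScoreDecomposition(contrib, np.arange(2), contrib)
            fl = make_flips(24, 400, seed=r)
            rej += mahalanobis_combine(sd, fl).p_two_sided <= 0.05
        lo, hi = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / reps), 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / reps)
        assert lo <= rej / reps <= hi


class TestLevelAndPower:
    def test_level_under_heteroscedastic_gaussian_errors(self, rng):
        # validity under variance misspecification: errors with sd ~ |x|, the
        # worst case for a test that trusts a homoscedastic variance estimate.
        # The flip test stays near nominal (exactness is only asymptotic once
        # a nuisance fit couples the contributions) while the naive OLS t-test
        # collapses (empirical level > 0.2 under this design).
        from scipy import stats

        reps = 2000
        rej_flip = rej_naive = 0
        n = 100
        for r in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n) * (0.2 + np.abs(x))  # null: no x effect
            X = np.column_stack([np.ones(n), x])
            sd = _null_decomposition("gaussian", X, y, tested=1)
            res = standardized_flip_stats(sd, make_flips(n, 500, seed=r))
            rej_flip += res.p_two_sided <= 0.05
            bhat = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ bhat
            se = np.sqrt(resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
            rej_naive += 2 * stats.t.sf(abs(bhat[1] / se), n - 2) <= 0.05
        assert rej_flip / reps <= 0.075
        assert rej_flip / reps >= 0.03
        assert rej_naive / reps > 2 * rej_flip / reps

    def test_power_monotone_in_effect_size(self, rng):
        n, reps = 40, 400
        rates = []
        for beta in (0.0, 0.3, 0.6, 1.2):
            rej = 0
            for r in range(reps):
                x = rng.normal(size=n)
                y = beta * x + rng.normal(size=n)
                X = np.column_stack([np.ones(n), x])
                sd = _null_decomposition("gaussian", X, y, tested=1)
                res = standardized_flip_stats(sd, make_flips(n, 300, seed=r))
                rej += res.p_two_sided <= 0.05
            rates.append(rej / reps)
        slack = 2 * np.sqrt(0.25 / reps)
        assert all(rates[i + 1] >= rates[i] - slack for i in range(3))
        assert rates[-1] > 0.9  # strong effect is essentially always detected
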