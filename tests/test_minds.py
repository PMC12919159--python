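"""Sampler correctness for the integrative subtyping model.

The conjugate conditional updates are checked one by one against dense
quadrature on one-parameter slices of the exact (augmented) conditional
densities; the full Gibbs chain is checked against a brute-force grid
posterior on a tiny decoupled instance; label alignment and the
information criterion are checked with planted constructions.
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mindsmci.minds import (
    MindsConfig,
    MindsModel,
    MindsResults,
    binary_row_posterior,
    center_posterior,
    continuous_row_posterior,
    latent_posterior,
    relabel_draws,
    sigma2_posterior,
    varimax_rotation,
)

PRIOR_VAR = 10.0


def _grid_moments(grid, logf):
    logf = logf - logf.max()
    w = np.exp(logf)
    w /= np.trapezoid(w, grid)
    mean = np.trapezoid(grid * w, grid)
    var = np.trapezoid((grid - mean) ** 2 * w, grid)
    return mean, var


def _conditional_slice(mean, cov, fixed_idx, fixed_val, free_idx):
    """Gaussian conditional of one coordinate given the others."""
    S11 = cov[free_idx, free_idx]
    S12 = cov[np.ix_([free_idx], fixed_idx)]
    S22 = cov[np.ix_(fixed_idx, fixed_idx)]
    delta = np.asarray(fixed_val) - mean[fixed_idx]
    mu = mean[free_idx] + (S12 @ np.linalg.solve(S22, delta))[0]
    var = S11 - (S12 @ np.linalg.solve(S22, S12.T))[0, 0]
    return mu, var


class TestConditionalQuadratureOracles:
    """Each analytic conditional matches dense quadrature to 1e-3."""

    def test_binary_row_intercept_slice(self, frozen_state):
        st_ = frozen_state
        prior_prec = np.full(st_["q"] + 1, 1.0 / PRIOR_VAR)
        mean, cov = binary_row_posterior(st_["U1"], st_["x"], st_["omega"], prior_prec)
        w_fixed = np.array([0.4, -0.2])
        mu_a, var_a = _conditional_slice(mean, cov, [0, 1], w_fixed, 2)
        grid = np.linspace(mu_a - 8 * np.sqrt(var_a), mu_a + 8 * np.sqrt(var_a), 6001)
        kappa = st_["x"] - 0.5
        psi = st_["u"] @ w_fixed
        logf = np.array(
            [
                np.sum(kappa * (psi + b) - st_["omega"] * (psi + b) ** 2 / 2)
                - b**2 / (2 * PRIOR_VAR)
                for b in grid
            ]
        )
        mu_q, var_q = _grid_moments(grid, logf)
        assert abs(mu_q - mu_a) < 1e-3
        assert abs(var_q - var_a) < 1e-3

    def test_continuous_row_loading_slice(self, frozen_state):
        st_ = frozen_state
        sigma2 = 0.49
        prior_prec = np.full(st_["q"] + 1, 1.0 / PRIOR_VAR)
        mean, cov = continuous_row_posterior(st_["U1"], st_["y"], sigma2, prior_prec)
        fixed = np.array([-0.1, 0.6])  # fix (w2, b); slice over w1
        mu_a, var_a = _conditional_slice(mean, cov, [1, 2], fixed, 0)
        grid = np.linspace(mu_a - 8 * np.sqrt(var_a), mu_a + 8 * np.sqrt(var_a), 6001)
        resid_base = st_["y"] - st_["u"][:, 1] * fixed[0] - fixed[1]
        logf = np.array(
            [
                -np.sum((resid_base - w1 * st_["u"][:, 0]) ** 2) / (2 * sigma2)
                - w1**2 / (2 * PRIOR_VAR)
                for w1 in grid
            ]
        )
        mu_q, var_q = _grid_moments(grid, logf)
        assert abs(mu_q - mu_a) < 1e-3
        assert abs(var_q - var_a) < 1e-3

    def test_latent_score_slice(self):
        rng = np.random.default_rng(5)
        q, p_b, p_c = 2, 3, 2
        Wb = rng.standard_normal((p_b, q))
        bb = rng.standard_normal(p_b) * 0.3
        Wc = rng.standard_normal((p_c, q))
        bc = rng.standard_normal(p_c) * 0.3
        sigma2 = np.array([0.8, 1.3])
        x = np.array([[1.0, 0.0, 1.0]])
        y = np.array([[0.4, -1.1]])
        omega = np.array([[0.21, 0.4, 0.15]])
        center = np.array([[0.5, -0.5]])
        kappa = x - 0.5
        mean, cov = latent_posterior(Wb, bb, Wc, bc, sigma2, omega, kappa, y, center)
        mu_a, var_a = _conditional_slice(mean[0], cov[0], [1], [0.3], 0)
        grid = np.linspace(mu_a - 8 * np.sqrt(var_a), mu_a + 8 * np.sqrt(var_a), 6001)
        logf = []
        for u1 in grid:
            u = np.array([u1, 0.3])
            psi = Wb @ u + bb
            lf = np.sum(kappa[0] * psi - omega[0] * psi**2 / 2)
            lf += -np.sum((y[0] - Wc @ u - bc) ** 2 / (2 * sigma2))
            lf += -np.sum((u - center[0]) ** 2) / 2
            logf.append(lf)
        mu_q, var_q = _grid_moments(grid, np.array(logf))
        assert abs(mu_q - mu_a) < 1e-3
        assert abs(var_q - var_a) < 1e-3

    def test_center_update_slice(self):
        rng = np.random.default_rng(9)
        members = rng.standard_normal((12, 1)) + 1.2
        mean, var = center_posterior(members, PRIOR_VAR)
        grid = np.linspace(mean[0] - 8 * np.sqrt(var), mean[0] + 8 * np.sqrt(var), 6001)
        logf = np.array(
            [
                -np.sum((members[:, 0] - m) ** 2) / 2 - m**2 / (2 * PRIOR_VAR)
                for m in grid
            ]
        )
        mu_q, var_q = _grid_moments(grid, logf)
        assert abs(mu_q - mean[0]) < 1e-3
        assert abs(var_q - var) < 1e-3

    def test_noise_variance_update_quadrature(self):
        rng = np.random.default_rng(13)
        resid = rng.standard_normal(60) * 0.9
        shape, scale = sigma2_posterior(resid, 2.0, 1.0)
        analytic_mean = scale / (shape - 1)
        grid = np.linspace(1e-3, 8, 40001)
        logf = (
            -(2.0 + 1) * np.log(grid)
            - 1.0 / grid
            - resid.size / 2 * np.log(grid)
            - np.sum(resid**2) / (2 * grid)
        )
        mu_q, _ = _grid_moments(grid, logf)
        assert abs(mu_q - analytic_mean) / analytic_mean < 1e-3


class TestTinyInstanceGridOracle:
    """On a decoupled 20-subject instance (loadings pinned to ~0) the Gibbs
    posterior means match brute-force grid integration."""

    @pytest.fixture(scope="class")
    def tiny_fit(self):
        rng = np.random.default_rng(31)
        x = (rng.random(20) < 0.35).astype(float)[:, None]
        y = 0.5 + rng.standard_normal((20, 2))
        cfg = MindsConfig(
            n_clusters=1,
            n_latent=1,
            n_iter=8000,
            n_burnin=2000,
            thin=1,
            prior_loading_var=1e-12,  # pins every loading to ~0: columns decouple
            seed=2,
        )
        fit = MindsModel(x, y, cfg).fit()
        return x, y, fit

    def test_binary_intercept_matches_grid_posterior(self, tiny_fit):
        x, _, fit = tiny_fit
        grid = np.linspace(-6, 6, 4001)
        k = x.sum()
        n = len(x)
        logf = (
            k * grid
            - n * np.log1p(np.exp(grid))
            - grid**2 / (2 * PRIOR_VAR)
        )
        mu_grid, _ = _grid_moments(grid, logf)
        assert abs(fit.intercepts_mean[0] - mu_grid) < 0.05

    def test_continuous_intercept_matches_grid_posterior(self, tiny_fit):
        _, y, fit = tiny_fit
        yl = y[:, 0]
        b_grid = np.linspace(-3, 3, 601)
        s_grid = np.linspace(0.02, 10, 801)
        B, S = np.meshgrid(b_grid, s_grid, indexing="ij")
        n = len(yl)
        logf = (
            -n / 2 * np.log(S)
            - ((yl[None, None, :] - B[..., None]) ** 2).sum(-1) / (2 * S)
            - B**2 / (2 * PRIOR_VAR)
            - (2.0 + 1) * np.log(S)
            - 1.0 / S
        )
        w = np.exp(logf - logf.max())
        mu_grid = (B * w).sum() / w.sum()
        assert abs(fit.intercepts_mean[1] - mu_grid) < 0.05


class TestModelInterface:
    def test_k1_reduces_to_factor_model(self, small_cohort):
        cohort, _, _ = small_cohort
        from mindsmci.simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS

        cfg = MindsConfig(n_clusters=1, n_latent=2, n_iter=120, n_burnin=40, thin=2, seed=1)
        fit = MindsModel(
            cohort[BINARY_COLUMNS].head(150), cohort[CONTINUOUS_COLUMNS].head(150), cfg
        ).fit()
        assert (fit.map_assignments == 1).all()
        assert np.allclose(fit.mixing_mean, 1.0)

    def test_fit_seed_determinism(self, small_cohort):
        cohort, _, _ = small_cohort
        from mindsmci.simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS

        cfg = MindsConfig(n_clusters=3, n_latent=2, n_iter=80, n_burnin=30, thin=2, seed=4)
        args = (cohort[BINARY_COLUMNS].head(120), cohort[CONTINUOUS_COLUMNS].head(120), cfg)
        a = MindsModel(*args).fit()
        b = MindsModel(*args).fit()
        np.testing.assert_array_equal(a.draws["z"], b.draws["z"])
        np.testing.assert_allclose(a.draws["W"], b.draws["W"])
        assert a.information_criterion() == b.information_criterion()

    def test_non_binary_values_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            MindsModel(np.array([[0.5]]), np.array([[1.0]]))

    def test_k_exceeding_n_rejected(self):
        cfg = MindsConfig(n_clusters=10, n_iter=10, n_burnin=5)
        with pytest.raises(ValueError, match="exceeds"):
            MindsModel(np.zeros((5, 2)), np.zeros((5, 2)), cfg)

    def test_trace_length_contract(self, small_cohort):
        cohort, _, _ = small_cohort
        from mindsmci.simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS

        cfg = MindsConfig(n_clusters=2, n_iter=100, n_burnin=40, thin=3, seed=0)
        fit = MindsModel(
            cohort[BINARY_COLUMNS].head(100), cohort[CONTINUOUS_COLUMNS].head(100), cfg
        ).fit()
        assert len(fit.ll_trace) == (100 - 40) // 3


class TestRelabeling:
    @pytest.fixture(scope="class")
    def fit(self, small_cohort):
        cohort, _, _ = small_cohort
        from mindsmci.simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS

        cfg = MindsConfig(n_clusters=4, n_latent=3, n_iter=220, n_burnin=100, thin=2, seed=6)
        return MindsModel(cohort[BINARY_COLUMNS], cohort[CONTINUOUS_COLUMNS], cfg).fit()

    def test_aligned_draws_unchanged_by_relabeling(self, fit):
        draws = {k: v.copy() for k, v in fit.draws.items()}
        relabel_draws(draws)  # already aligned at end of fit
        np.testing.assert_allclose(draws["mu"], fit.draws["mu"])
        np.testing.assert_array_equal(draws["z"], fit.draws["z"])

    def test_planted_permutation_restored(self, fit):
        rng = np.random.default_rng(3)
        draws = {k: v.copy() for k, v in fit.draws.items()}
        T, K, _ = draws["mu"].shape
        for t in range(T // 2):  # scramble half the draws
            perm = rng.permutation(K)
            draws["mu"][t] = draws["mu"][t][perm]
            draws["pi"][t] = draws["pi"][t][perm]
            inv = np.empty(K, dtype=int)
            inv[perm] = np.arange(K)
            draws["z"][t] = inv[draws["z"][t]]
        sd_scrambled = draws["mu"].std(axis=0).mean()
        relabel_draws(draws)
        sd_fixed = draws["mu"].std(axis=0).mean()
        assert sd_fixed <= sd_scrambled
        # centers realigned with the unscrambled fit up to a global relabeling
        cost = ((draws["mu"].mean(0)[:, None, :] - fit.draws["mu"].mean(0)[None]) ** 2).sum(-1)
        from scipy.optimize import linear_sum_assignment

        r, c = linear_sum_assignment(cost)
        assert cost[r, c].sum() < 0.05 * K

    def test_coclustering_invariant_under_relabeling(self, fit):
        rng = np.random.default_rng(8)
        draws = {k: v.copy() for k, v in fit.draws.items()}
        T, K, _ = draws["mu"].shape
        for t in range(T):
            perm = rng.permutation(K)
            inv = np.empty(K, dtype=int)
            inv[perm] = np.arange(K)
            draws["z"][t] = inv[draws["z"][t]]
        scrambled = MindsResults(fit.model, fit.config, draws, fit.ll_trace, fit.u_mean)
        np.testing.assert_array_equal(scrambled.coclustering(), fit.coclustering())

    def test_coclustering_symmetric_unit_diagonal(self, fit):
        C = fit.coclustering()
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)


class TestInformationCriterion:
    def test_extra_empty_cluster_strictly_increases_ic(self, small_cohort):
        cohort, _, _ = small_cohort
        from mindsmci.simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS

        cfg = MindsConfig(n_clusters=2, n_latent=2, n_iter=150, n_burnin=60, thin=2, seed=5)
        fit = MindsModel(
            cohort[BINARY_COLUMNS].head(200), cohort[CONTINUOUS_COLUMNS].head(200), cfg
        ).fit()
        draws = {k: v.copy() for k, v in fit.draws.items()}
        T, K, q = draws["mu"].shape
        far = np.full((T, 1, q), 50.0)  # empty component far from all data
        draws["mu"] = np.concatenate([draws["mu"], far], axis=1)
        eps = 1e-12
        draws["pi"] = np.concatenate([draws["pi"] * (1 - eps), np.full((T, 1), eps)], axis=1)
        bigger = MindsResults(
            fit.model,
            dataclasses.replace(cfg, n_clusters=K + 1),
            draws,
            fit.ll_trace,
            fit.u_mean,
        )
        assert bigger.information_criterion() > fit.information_criterion()
        assert bigger.n_free_parameters == fit.n_free_parameters + q + 1

    def test_parameter_count_hand_computed(self, small_cohort):
        cohort, _, _ = small_cohort
        from mindsmci.simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS

        cfg = MindsConfig(n_clusters=3, n_latent=2, n_iter=30, n_burnin=10, thin=1, seed=0)
        fit = MindsModel(
            cohort[BINARY_COLUMNS].head(40), cohort[CONTINUOUS_COLUMNS].head(40), cfg
        ).fit()
        p, p_c, K, q = 23, 14, 3, 2
        assert fit.n_free_parameters == p * (q + 1) + p_c + K * q + (K - 1)


class TestLoadingSummary:
    def test_unit_norm_and_sign_convention(self, small_cohort):
        cohort, _, _ = small_cohort
        from mindsmci.simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS

        cfg = MindsConfig(n_clusters=2, n_latent=3, n_iter=120, n_burnin=50, thin=2, seed=9)
        fit = MindsModel(
            cohort[BINARY_COLUMNS].head(200), cohort[CONTINUOUS_COLUMNS].head(200), cfg
        ).fit()
        df, tops = fit.loading_summary()
        norms = np.linalg.norm(df.to_numpy(), axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        for col in df.columns:
            v = df[col].to_numpy()
            assert v[np.abs(v).argmax()] > 0
        assert set(tops) == set(df.columns)

    def test_varimax_returns_orthogonal_rotation(self):
        rng = np.random.default_rng(2)
        W = rng.standard_normal((20, 3))
        R = varimax_rotation(W)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)

    def test_all_positive_single_column_unchanged_by_sign(self):
        W = np.abs(np.random.default_rng(0).standard_normal((6, 1)))
        R = varimax_rotation(W)
        flipped = W @ R
        assert np.all(flipped * np.sign(flipped[np.abs(flipped[:, 0]).argmax(), 0]) > 0)


class TestChainHealth:
    def test_no_monotone_drift_after_burnin(self, small_cohort):
        """Slope of a linear fit to the post-burn-in log-likelihood trace is
        statistically indistinguishable from zero on well-specified data."""
        cohort, _, _ = small_cohort
        from mindsmci.simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS

        cfg = MindsConfig(n_clusters=4, n_latent=3, n_iter=1100, n_burnin=300, thin=2, seed=12)
        fit = MindsModel(cohort[BINARY_COLUMNS], cohort[CONTINUOUS_COLUMNS], cfg).fit()
        # the raw trace is heavily autocorrelated; regress on batch means so
        # the slope's standard error reflects the chain's effective sample size
        trace = fit.ll_trace
        n_batches = 10
        batches = np.array_split(trace, n_batches)
        means = np.array([b.mean() for b in batches])
        res = stats.linregress(np.arange(n_batches), means)
        crit = stats.t.ppf(0.995, n_batches - 2)
        assert abs(res.slope) < crit * res.stderr
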