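"""MINDS: Bayesian integrative subtyping of mixed binary/continuous data.

The model couples modality-specific likelihoods through a shared latent
construct.  Subject i carries a latent score u_i in R^q and a cluster label
z_i in {1..K}:

    z_i ~ Categorical(pi),            pi ~ Dirichlet(alpha)
    u_i | z_i ~ N(mu_{z_i}, I_q),     mu_k ~ N(0, c I_q)
    x_ij ~ Bernoulli( logistic(b_j + w_j . u_i) )      (binary block)
    y_il ~ N( b_l + v_l . u_i, sigma_l^2 )             (continuous block)

with Normal priors on loadings/intercepts and Inverse-Gamma on sigma_l^2.
Pólya–Gamma augmentation (omega_ij ~ PG(1, psi_ij)) renders every
conditional Gaussian / Inverse-Gamma / Dirichlet / categorical, so the
posterior is explored by a pure Gibbs sweep.

The latent covariance is fixed at the identity for scale identifiability;
rotational ambiguity is left to the sampler (clustering and the information
criterion are rotation invariant) and resolved only at reporting time by
the column ordering/sign convention of :meth:`MindsResults.loading_summary`.

Cluster-count selection uses a BIC-style criterion on a Laplace
approximation of the observed-data likelihood at posterior means,

    IC(K) = -2 * sum_i [ log p(x_i, y_i | u-hat_i, theta-hat)
                         + log sum_k pi-hat_k N(u-hat_i; mu-hat_k, I)
                         + q/2 log 2 pi - 1/2 log det(I + J_i) ]
            + d log n,

where J_i is the Fisher information of the modality likelihoods in u at
u-hat_i.  The log-determinant is the Laplace volume factor of integrating
the latent score out; without it a smaller K can cheat the criterion by
shrinking the latent scale along a merged-cluster direction while inflating
the loadings (the conditional likelihood is invariant to that rescaling,
the marginal likelihood is not).  d counts free parameters (loadings,
intercepts, noise variances, centers, mixing weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .polya_gamma import sample_pg

__all__ = [
    "MindsConfig",
    "MindsModel",
    "MindsResults",
    "fit_minds",
    "information_criterion",
    "select_k",
    "relabel_draws",
]

_CLIP = 30.0
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MindsConfig:
    """Sampler and prior settings.

    Defaults: weakly-informative Normal(0, 10) priors on loadings,
    intercepts and centers, Inverse-Gamma(2, 1) on noise variances,
    symmetric Dirichlet(1) on mixing weights; 3,000 sweeps with 1,000
    burn-in thinned by 2.
    """

    n_clusters: int = 4
    n_latent: int = 3
    n_iter: int = 3000
    n_burnin: int = 1000
    thin: int = 2
    prior_loading_var: float = 10.0
    prior_intercept_var: float = 10.0
    prior_center_var: float = 10.0
    dirichlet_concentration: float = 1.0
    inv_gamma_shape: float = 2.0
    inv_gamma_scale: float = 1.0
    seed: int = 0

    def validate(self):
        if self.n_iter <= self.n_burnin:
            raise ValueError("n_iter must exceed n_burnin")
        for name in ("prior_loading_var", "prior_intercept_var", "prior_center_var"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_clusters < 1 or self.n_latent < 1:
            raise ValueError("n_clusters and n_latent must be >= 1")


# ----------------------------------------------------------------------
# conditional posteriors (exact conjugate forms; unit-testable one by one)

def binary_row_posterior(U1, x_col, omega_col, prior_prec):
    """Gaussian conditional of one binary row's (loadings, intercept).

    Given PG auxiliaries omega, the Bernoulli-logistic likelihood in
    beta = (w_j, b_j) is Gaussian with precision U1' diag(omega) U1 and
    natural parameter U1' kappa, kappa = x - 1/2.
    Returns ``(mean, cov)``.
    """
    kappa = x_col - 0.5
    prec = U1.T @ (U1 * omega_col[:, None]) + np.diag(prior_prec)
    cov = np.linalg.inv(prec)
    mean = cov @ (U1.T @ kappa)
    return mean, cov


def continuous_row_posterior(U1, y_col, sigma2, prior_prec):
    """Gaussian conditional of one continuous row's (loadings, intercept)."""
    prec = U1.T @ U1 / sigma2 + np.diag(prior_prec)
    cov = np.linalg.inv(prec)
    mean = cov @ (U1.T @ y_col / sigma2)
    return mean, cov


def latent_posterior(Wb, b_bin, Wc, b_cont, sigma2, omega, kappa, Y, centers):
    """Batched Gaussian conditional of every u_i.

    Precision  A_i = I + sum_j omega_ij w_j w_j' + sum_l v_l v_l'/sigma_l^2
    Natural    h_i = mu_{z_i} + sum_j w_j (kappa_ij - omega_ij b_j)
                     + sum_l v_l (y_il - b_l)/sigma_l^2
    Returns ``(mean, cov)`` with shapes (n, q) and (n, q, q).
    """
    n = omega.shape[0] if omega is not None else Y.shape[0]
    q = (Wb if Wb is not None else Wc).shape[1]
    A = np.broadcast_to(np.eye(q), (n, q, q)).copy()
    h = centers.copy()
    if Wb is not None and Wb.size:
        A += np.einsum("ij,jq,jr->iqr", omega, Wb, Wb)
        h += (kappa - omega * b_bin) @ Wb
    if Wc is not None and Wc.size:
        Vs = Wc / sigma2[:, None]
        A += np.broadcast_to(Wc.T @ Vs, (n, q, q))
        h += (Y - b_cont) @ Vs
    cov = np.linalg.inv(A)
    mean = np.einsum("iqr,ir->iq", cov, h)
    return mean, cov


def center_posterior(u_members, prior_var):
    """Gaussian conditional of one cluster center (shared across dims)."""
    n_k = u_members.shape[0]
    var = 1.0 / (n_k + 1.0 / prior_var)
    mean = var * u_members.sum(axis=0) if n_k else np.zeros(u_members.shape[1])
    return mean, var

def sigma2_posterior(resid, shape0, scale0):
    """Inverse-Gamma conditional of one noise variance; returns (shape, scale)."""
    return shape0 + resid.size / 2.0, scale0 + 0.5 * float(resid @ resid)


# ----------------------------------------------------------------------
class MindsModel:
    """Joint clustering + dimension-reduction model for a mixed cohort.

    Parameters
    ----------
    binary : array-like (n, p_b) of 0/1
        Comorbidity / lifestyle indicators.
    continuous : array-like (n, p_c)
        Standardized scale scores (higher = worse).
    config : MindsConfig
    """

    def __init__(self, binary, continuous, config: MindsConfig | None = None):
        self.config = config or MindsConfig()
        self.config.validate()
        self.binary = self._check_binary(binary)
        self.continuous = np.asarray(continuous, dtype=float)
        if self.continuous.ndim == 1:
            self.continuous = self.continuous[:, None]
        if self.binary.shape[0] != self.continuous.shape[0]:
            raise ValueError("binary and continuous blocks disagree on n")
        self.n = self.binary.shape[0]
        if self.config.n_clusters > self.n:
            raise ValueError("n_clusters exceeds number of subjects")
        self.binary_names = list(getattr(binary, "columns", [f"bin_{j}" for j in range(self.binary.shape[1])]))
        self.continuous_names = list(getattr(continuous, "columns", [f"cont_{l}" for l in range(self.continuous.shape[1])]))

    @staticmethod
    def _check_binary(binary):
        arr = np.asarray(binary, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("binary block must contain only 0/1 values")
        return arr

    # ------------------------------------------------------------------
    def _initial_state(self, rng):
        from sklearn.cluster import KMeans
        from sklearn.decomposition import PCA

        cfg = self.config
        q, K = cfg.n_latent, cfg.n_clusters
        X = np.column_stack([self.binary - self.binary.mean(axis=0), self.continuous])
        q_eff = min(q, X.shape[1], self.n - 1)
        u = np.zeros((self.n, q))
        if q_eff:
            pcs = PCA(n_components=q_eff, random_state=0).fit_transform(X)
            sd = pcs.std(axis=0)
            sd[sd == 0] = 1.0
            u[:, :q_eff] = pcs / sd * 1.5
        if K > 1:
            km = KMeans(n_clusters=K, n_init=10, random_state=0).fit(u)
            z = km.labels_.astype(np.int64)
            mu = km.cluster_centers_.copy()
        else:
            z = np.zeros(self.n, dtype=np.int64)
            mu = u.mean(axis=0, keepdims=True).copy()
        p_b, p_c = self.binary.shape[1], self.continuous.shape[1]
        prev = self.binary.mean(axis=0).clip(0.02, 0.98)
        state = {
            "u": u,
            "z": z,
            "mu": mu,
            "pi": np.full(K, 1.0 / K),
            "Wb": np.zeros((p_b, q)),
            "bb": np.log(prev / (1 - prev)),
            "Wc": np.zeros((p_c, q)),
            "bc": self.continuous.mean(axis=0).copy(),
            "sigma2": np.ones(p_c),
        }
        return state

    # ------------------------------------------------------------------
    def fit(self, n_iter=None, n_burnin=None, thin=None, seed=None, progress=False) -> "MindsResults":
        """Run the full Gibbs sweep and return posterior summaries.

        Identical seed (and data/config) gives an identical fit.
        """
        cfg = self.config
        if any(v is not None for v in (n_iter, n_burnin, thin, seed)):
            cfg = replace(
                cfg,
                n_iter=n_iter if n_iter is not None else cfg.n_iter,
                n_burnin=n_burnin if n_burnin is not None else cfg.n_burnin,
                thin=thin if thin is not None else cfg.thin,
                seed=seed if seed is not None else cfg.seed,
            )
            cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        K, q = cfg.n_clusters, cfg.n_latent
        n, p_b, p_c = self.n, self.binary.shape[1], self.continuous.shape[1]
        X, Y = self.binary, self.continuous
        kappa = X - 0.5
        st = self._initial_state(rng)

        prior_prec = np.concatenate(
            [np.full(q, 1.0 / cfg.prior_loading_var), [1.0 / cfg.prior_intercept_var]]
        )
        n_keep = (cfg.n_iter - cfg.n_burnin) // cfg.thin
        draws = {
            "W": np.empty((n_keep, p_b + p_c, q)),
            "b": np.empty((n_keep, p_b + p_c)),
            "sigma2": np.empty((n_keep, p_c)),
            "mu": np.empty((n_keep, K, q)),
            "pi": np.empty((n_keep, K)),
            "z": np.empty((n_keep, n), dtype=np.int16),
        }
        ll_trace = np.empty(n_keep)
        u_sum = np.zeros((n, q))
        keep = 0

        for it in range(cfg.n_iter):
            # (1) PG auxiliaries for every binary cell
            psi = np.clip(st["u"] @ st["Wb"].T + st["bb"], -_CLIP, _CLIP)
            omega = sample_pg(psi, rng)

            # (2) loadings + intercepts, row by row (conjugate Gaussian)
            U1 = np.column_stack([st["u"], np.ones(n)])
            for j in range(p_b):
                mean, cov = binary_row_posterior(U1, X[:, j], omega[:, j], prior_prec)
                beta = rng.multivariate_normal(mean, cov, method="cholesky")
                st["Wb"][j], st["bb"][j] = beta[:q], beta[q]
            for l in range(p_c):
                mean, cov = continuous_row_posterior(U1, Y[:, l], st["sigma2"][l], prior_prec)
                beta = rng.multivariate_normal(mean, cov, method="cholesky")
                st["Wc"][l], st["bc"][l] = beta[:q], beta[q]

            # (3) latent scores (batched Gaussian)
            mean_u, cov_u = latent_posterior(
                st["Wb"], st["bb"], st["Wc"], st["bc"], st["sigma2"],
                omega, kappa, Y, st["mu"][st["z"]],
            )
            Lc = np.linalg.cholesky(cov_u)
            st["u"] = mean_u + np.einsum("iqr,ir->iq", Lc, rng.standard_normal((n, q)))

            # (4) cluster centers
            for k in range(K):
                members = st["u"][st["z"] == k]
                if members.shape[0]:
                    mean, var = center_posterior(members, cfg.prior_center_var)
                    st["mu"][k] = mean + np.sqrt(var) * rng.standard_normal(q)
                else:  # empty cluster: draw the center from its prior
                    st["mu"][k] = np.sqrt(cfg.prior_center_var) * rng.standard_normal(q)

            # (5) noise variances
            resid = Y - st["u"] @ st["Wc"].T - st["bc"]
            for l in range(p_c):
                shape, scale = sigma2_posterior(resid[:, l], cfg.inv_gamma_shape, cfg.inv_gamma_scale)
                st["sigma2"][l] = scale / rng.gamma(shape, 1.0)

            # (6) mixing weights
            counts = np.bincount(st["z"], minlength=K)
            st["pi"] = rng.dirichlet(cfg.dirichlet_concentration + counts)

            # (7) assignments
            if K > 1:
                d2 = ((st["u"][:, None, :] - st["mu"][None, :, :]) ** 2).sum(axis=2)
                logp = np.log(st["pi"]) - 0.5 * d2
                logp -= logp.max(axis=1, keepdims=True)
                prob = np.exp(logp)
                prob /= prob.sum(axis=1, keepdims=True)
                cum = prob.cumsum(axis=1)
                st["z"] = (rng.random((n, 1)) < cum).argmax(axis=1)

            if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                draws["W"][keep] = np.vstack([st["Wb"], st["Wc"]])
                draws["b"][keep] = np.concatenate([st["bb"], st["bc"]])
                draws["sigma2"][keep] = st["sigma2"]
                draws["mu"][keep] = st["mu"]
                draws["pi"][keep] = st["pi"]
                draws["z"][keep] = st["z"]
                u_sum += st["u"]
                ll_trace[keep] = _plugin_loglik(
                    X, Y, st["u"], st["Wb"], st["bb"], st["Wc"], st["bc"],
                    st["sigma2"], st["pi"], st["mu"],
                )
                keep += 1

        relabel_draws(draws)
        return MindsResults(self, cfg, draws, ll_trace, u_sum / max(keep, 1))


def _plugin_loglik(X, Y, u, Wb, bb, Wc, bc, sigma2, pi, mu):
    """Observed-data log-likelihood at plug-in latent scores.

    Bernoulli + Gaussian modality terms plus the latent mixture density
    log sum_k pi_k N(u_i; mu_k, I).
    """
    psi = np.clip(u @ Wb.T + bb, -_CLIP, _CLIP)
    ll = float((X * psi - np.log1p(np.exp(psi))).sum())
    resid = Y - u @ Wc.T - bc
    ll += float(
        (-0.5 * _LOG2PI - 0.5 * np.log(sigma2) - 0.5 * resid**2 / sigma2).sum()
    )
    q = u.shape[1]
    d2 = ((u[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    comp = np.log(np.maximum(pi, 1e-300)) - 0.5 * q * _LOG2PI - 0.5 * d2
    ll += float(logsumexp(comp, axis=1).sum())
    return ll


def _joint_logdensity(X, Y, Wb, bb, Wc, bc, sigma2, mu_k, U):
    """g_ik(u) = log p(x_i, y_i | u) + log N(u; mu_k, I) at U (n, q)."""
    psi = np.clip(U @ Wb.T + bb, -_CLIP, _CLIP)
    g = (X * psi - np.log1p(np.exp(psi))).sum(axis=1)
    resid = Y - U @ Wc.T - bc
    g += (-0.5 * _LOG2PI - 0.5 * np.log(sigma2) - 0.5 * resid**2 / sigma2).sum(axis=1)
    q = U.shape[1]
    g += -0.5 * q * _LOG2PI - 0.5 * ((U - mu_k) ** 2).sum(axis=1)
    return g


def _laplace_loglik(X, Y, u, Wb, bb, Wc, bc, sigma2, pi, mu, n_newton=25):
    """Laplace-approximate observed-data log-likelihood at plug-in parameters.

    For every subject i and component k the latent score is integrated out
    by a Laplace approximation at the mode of the strictly concave
    integrand g_ik(u) = log p(x_i, y_i | u) + log N(u; mu_k, I) (found by
    batched Newton), then components are mixed:

        ll_i = logsumexp_k [ log pi_k + g_ik(u*_ik)
                             + q/2 log 2pi - 1/2 log det H_ik ].

    Unlike a plug-in conditional likelihood this charges the correct
    Occam volume for the latent scores, so merging clusters cannot be
    compensated by shrinking the latent scale against inflated loadings.
    """
    n, q = u.shape
    K = mu.shape[0]
    Cc = Wc.T @ (Wc / sigma2[:, None])  # continuous-block information (q, q)
    eye = np.eye(q)
    comp_ll = np.empty((n, K))
    for k in range(K):
        U = u.copy()  # warm start at the posterior-mean scores
        for _ in range(n_newton):
            psi = np.clip(U @ Wb.T + bb, -_CLIP, _CLIP)
            prob = 1.0 / (1.0 + np.exp(-psi))
            grad = (
                (X - prob) @ Wb
                + (Y - U @ Wc.T - bc) @ (Wc / sigma2[:, None])
                - (U - mu[k])
            )
            H = np.einsum("ij,jq,jr->iqr", prob * (1 - prob), Wb, Wb) + Cc + eye
            step = np.linalg.solve(H, grad[..., None])[..., 0]
            U = U + step
            if np.max(np.abs(step)) < 1e-8:
                break
        g = _joint_logdensity(X, Y, Wb, bb, Wc, bc, sigma2, mu[k], U)
        psi = np.clip(U @ Wb.T + bb, -_CLIP, _CLIP)
        prob = 1.0 / (1.0 + np.exp(-psi))
        H = np.einsum("ij,jq,jr->iqr", prob * (1 - prob), Wb, Wb) + Cc + eye
        _, logdet = np.linalg.slogdet(H)
        comp_ll[:, k] = g + 0.5 * q * _LOG2PI - 0.5 * logdet
    return float(logsumexp(np.log(np.maximum(pi, 1e-300)) + comp_ll, axis=1).sum())


def varimax_rotation(W, max_iter=200, tol=1e-8):
    """Orthogonal varimax rotation matrix for a p x q loading matrix.

    The likelihood is invariant under joint orthogonal rotation of
    (loadings, latent scores, centers); varimax picks the member of that
    equivalence class with the sparsest (most interpretable) columns, the
    standard identification for reported factor loadings.
    """
    W = np.asarray(W, dtype=float)
    p, q = W.shape
    R = np.eye(q)
    if q == 1:
        return R
    var_old = 0.0
    for _ in range(max_iter):
        L = W @ R
        grad = W.T @ (L**3 - L * (L**2).sum(axis=0) / p)
        U, s, Vt = np.linalg.svd(grad)
        R = U @ Vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return R


def relabel_draws(draws):
    """Align mixture labels across retained draws (in place).

    Each draw's clusters are permuted to minimize the total squared
    Euclidean distance between its centers and a running posterior-mean
    reference; the assignment is solved exactly (Hungarian algorithm).
    Label-symmetric summaries (co-clustering) are invariant under this.
    """
    mu, pi, z = draws["mu"], draws["pi"], draws["z"]
    T, K, _ = mu.shape
    if K == 1 or T == 0:
        return draws
    ref = mu[0].copy()
    ref_n = 1
    for t in range(T):
        cost = ((mu[t][:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
        row, col = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=int)
        perm[col] = row  # draw-label perm[c] plays reference role c
        mu[t] = mu[t][perm]
        pi[t] = pi[t][perm]
        inv = np.empty(K, dtype=int)
        inv[perm] = np.arange(K)
        z[t] = inv[z[t]]
        ref = (ref * ref_n + mu[t]) / (ref_n + 1)
        ref_n += 1
    return draws


# ----------------------------------------------------------------------
class MindsResults:
    """Posterior summaries of a MINDS fit (statsmodels-style results)."""

    def __init__(self, model, config, draws, ll_trace, u_mean):
        self.model = model
        self.config = config
        self.draws = draws
        self.ll_trace = ll_trace
        self.u_mean = u_mean

    # posterior means -------------------------------------------------
    @property
    def loadings_mean(self):
        return self.draws["W"].mean(axis=0)

    @property
    def intercepts_mean(self):
        return self.draws["b"].mean(axis=0)

    @property
    def sigma2_mean(self):
        return self.draws["sigma2"].mean(axis=0)

    @property
    def centers_mean(self):
        return self.draws["mu"].mean(axis=0)

    @property
    def mixing_mean(self):
        return self.draws["pi"].mean(axis=0)

    def credible_interval(self, name, level=0.95):
        lo = (1 - level) / 2
        return np.quantile(self.draws[name], [lo, 1 - lo], axis=0)

    @property
    def map_assignments(self):
        """Per-subject posterior-mode cluster label (1-based)."""
        z = self.draws["z"]
        K = self.config.n_clusters
        counts = np.stack([(z == k).sum(axis=0) for k in range(K)])
        return counts.argmax(axis=0) + 1

    def coclustering(self):
        """Posterior probability that two subjects share a cluster (n x n)."""
        z = self.draws["z"]
        T, n = z.shape
        C = np.zeros((n, n))
        for t in range(T):
            C += z[t][:, None] == z[t][None, :]
        return C / T

    # information criterion --------------------------------------------
    @property
    def n_free_parameters(self):
        p = self.model.binary.shape[1] + self.model.continuous.shape[1]
        p_c = self.model.continuous.shape[1]
        K, q = self.config.n_clusters, self.config.n_latent
        return p * (q + 1) + p_c + K * q + (K - 1)

    def information_criterion(self):
        """-2 * Laplace observed-data log-likelihood + d log n (lower = better)."""
        p_b = self.model.binary.shape[1]
        W, b = self.loadings_mean, self.intercepts_mean
        ll = _laplace_loglik(
            self.model.binary,
            self.model.continuous,
            self.u_mean,
            W[:p_b],
            b[:p_b],
            W[p_b:],
            b[p_b:],
            self.sigma2_mean,
            self.mixing_mean,
            self.centers_mean,
        )
        return -2.0 * ll + self.n_free_parameters * np.log(self.model.n)

    # reporting ---------------------------------------------------------
    def rotated_loadings(self):
        """Varimax-aligned posterior quantities.

        Returns ``(W, u, mu)``: the posterior-mean loadings, latent scores
        and cluster centers jointly rotated to the varimax orientation (the
        likelihood-invariant representative with the sparsest loadings).
        """
        R = varimax_rotation(self.loadings_mean)
        return self.loadings_mean @ R, self.u_mean @ R, self.centers_mean @ R

    def loading_summary(self, top=5, rotate=True):
        """Standardized loading matrix and top features per construct.

        Varimax-aligned posterior-mean loadings with columns ordered by
        explained variance, scaled to unit norm, and sign-flipped so each
        column's largest-magnitude entry is positive.

        Returns ``(loadings_df, top_features)``.
        """
        W = self.rotated_loadings()[0] if rotate else self.loadings_mean.copy()
        order = np.argsort(-(W**2).sum(axis=0))
        W = W[:, order]
        norms = np.linalg.norm(W, axis=0)
        norms[norms == 0] = 1.0
        W = W / norms
        for c in range(W.shape[1]):
            if W[np.abs(W[:, c]).argmax(), c] < 0:
                W[:, c] = -W[:, c]
        names = self.model.binary_names + self.model.continuous_names
        df = pd.DataFrame(W, index=names, columns=[f"LC{c + 1}" for c in range(W.shape[1])])
        tops = {
            col: df[col].abs().sort_values(ascending=False).head(top).index.tolist()
            for col in df.columns
        }
        return df, tops

    def summary(self):
        """Plain-text fit summary."""
        lines = [
            "MINDS fit summary",
            "=" * 50,
            f"subjects: {self.model.n}   clusters: {self.config.n_clusters}   latent dim: {self.config.n_latent}",
            f"retained draws: {self.ll_trace.shape[0]} (of {self.config.n_iter} sweeps, burn-in {self.config.n_burnin}, thin {self.config.thin})",
            f"information criterion: {self.information_criterion():.1f}",
            f"mean posterior log-likelihood: {self.ll_trace.mean():.1f}",
            "cluster sizes (MAP): "
            + ", ".join(
                f"{k + 1}: {(self.map_assignments == k + 1).sum()}"
                for k in range(self.config.n_clusters)
            ),
            "mixing weights (posterior mean): "
            + np.array2string(self.mixing_mean, precision=3),
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
def fit_minds(binary, continuous, config: MindsConfig | None = None, **fit_kwargs) -> MindsResults:
    """Convenience wrapper: build a :class:`MindsModel` and fit it."""
    return MindsModel(binary, continuous, config).fit(**fit_kwargs)


def information_criterion(fit: MindsResults) -> float:
    return fit.information_criterion()


def select_k(binary, continuous, k_range, config: MindsConfig | None = None, **fit_kwargs):
    """Fit every K in ``k_range`` and pick the IC minimizer.

    Each K is run with a deterministic seed offset (base seed + 97 * K) so
    fits are independent but reproducible.  Returns ``(best_k, table)`` with
    the IC table as a DataFrame.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be nonempty")
    base = config or MindsConfig()
    rows = []
    fits = {}
    for K in k_range:
        cfg_k = replace(base, n_clusters=K, seed=base.seed + 97 * K)
        fit = MindsModel(binary, continuous, cfg_k).fit(**fit_kwargs)
        ic = fit.information_criterion()
        rows.append({"K": K, "IC": ic, "mean_loglik": float(fit.ll_trace.mean())})
        fits[K] = fit
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["IC"].idxmin(), "K"])
    return best_k, table, fits
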