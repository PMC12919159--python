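"""Debiased treatment-effect estimation on log time-to-MCI.

Implements the causal stage of the pipeline: the average treatment effect
(ATE) of a binary medication exposure on the logarithm of observed
follow-up time, and group average treatment effects (GATEs) within
data-driven subtypes, using

* an at-risk set defined by a fixed cutoff tau (default 48 months):
  subjects with an event before tau, or still under observation beyond it;
* inverse-probability-of-censoring weights (IPCW) from a proportional-
  hazards censoring model on treatment and covariates, evaluated at
  min(T, tau) and truncated at an upper quantile;
* a cross-fitted interactive regression model (IRM): per fold, nuisance
  fits of the propensity m(x) = P(D=1 | X) and outcome regressions
  g(d, x) = E[Y | D=d, X] on the training folds, evaluated on the held-out
  fold, combined in the doubly-robust (AIPW) score

      psi_i = g(1,x_i) - g(0,x_i)
              + D_i (Y_i - g(1,x_i)) / m(x_i)
              - (1-D_i)(Y_i - g(0,x_i)) / (1 - m(x_i)),

  with theta = sum w_i psi_i / sum w_i (IPCW weights w) and an
  influence-function standard error.

Exponentiating theta gives a geometric-mean time ratio: the multiplicative
prolongation (or shortening) of MCI-free time associated with treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.ensemble import HistGradientBoostingClassifier, HistGradientBoostingRegressor
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold

from .simulate import BINARY_COLUMNS, DEMOGRAPHIC_COLUMNS, TREATMENT_COLUMNS

__all__ = [
    "AtRiskSet",
    "IpcwWeights",
    "DmlResults",
    "define_at_risk",
    "fit_censoring_weights",
    "TreatmentEffectModel",
    "dml_irm_ate",
    "gate_by_subtype",
    "time_ratio",
    "default_confounders",
]

_Z = 1.959964  # two-sided 95% normal quantile


def default_confounders(treatment: str) -> list:
    """Demographics + baseline comorbidities + the *other* medication flags."""
    others = [c for c in TREATMENT_COLUMNS if c != treatment]
    comorbidities = BINARY_COLUMNS[:7]
    return DEMOGRAPHIC_COLUMNS + comorbidities + others


@dataclass
class AtRiskSet:
    """Complete-case view of the cohort under the cutoff-tau rule."""

    data: pd.DataFrame  # full cohort (censoring model needs every row)
    complete: np.ndarray  # bool; event before tau, or observed beyond tau
    y: np.ndarray  # log observed time, NaN where not complete
    tau: float

    @property
    def n_complete(self) -> int:
        return int(self.complete.sum())


def define_at_risk(cohort, tau=48.0, time_col="observed_time_months", event_col="event_indicator"):
    """Apply the fixed-cutoff at-risk rule.

    Complete rows are those with an event strictly before ``tau`` or an
    observed time of at least ``tau``; rows censored event-free before
    ``tau`` stay in ``data`` (the censoring model uses them) but are not
    complete.  Y is the log of observed time in months.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = cohort[time_col].to_numpy(dtype=float)
    e = cohort[event_col].to_numpy()
    complete = ((e == 1) & (t < tau)) | (t >= tau)
    y = np.where(complete, np.log(np.maximum(t, 1e-12)), np.nan)
    if not np.all(np.isfinite(y[complete])):
        raise ValueError("non-finite log observed time among complete rows")
    return AtRiskSet(data=cohort, complete=complete, y=y, tau=float(tau))


@dataclass
class IpcwWeights:
    """Per-subject censoring weights 1 / S_c(min(T, tau) | D, X)."""

    weights: np.ndarray  # aligned with the full cohort; NaN where not complete
    model_description: str
    truncation_quantile: float
    truncated_at: float


def fit_censoring_weights(
    cohort,
    tau=48.0,
    covariates=None,
    treatment=None,
    time_col="observed_time_months",
    event_col="event_indicator",
    truncation_quantile=0.99,
):
    """IPCW from a proportional-hazards censoring model.

    Censoring (the complement of the event indicator) is modeled as the
    outcome of a Cox fit on treatment and covariates using every row; the
    weight of a complete row is 1 / S_c(min(T, tau)-) evaluated from the
    Breslow baseline, then truncated at the ``truncation_quantile`` of the
    complete-row weights.  With no censoring events all weights are 1.
    """
    covariates = list(covariates or [])
    cols = ([treatment] if treatment else []) + covariates
    at_risk = define_at_risk(cohort, tau, time_col, event_col)
    t = cohort[time_col].to_numpy(dtype=float)
    # only the censoring process on [0, tau] matters for weights evaluated at
    # min(T, tau): truncate follow-up at tau so late administrative censoring
    # cannot dilute the covariate effects of early dropout
    t_tau = np.minimum(t, tau)
    cens = ((cohort[event_col].to_numpy() == 0) & (t < tau)).astype(int)
    if cens.sum() == 0 or not cols:
        w = np.where(at_risk.complete, 1.0, np.nan)
        return IpcwWeights(
            w, "no censoring observed before tau; unit weights", truncation_quantile, np.inf
        )

    df = cohort[cols].astype(float).copy()
    df["_time"] = t_tau
    df["_cens"] = cens
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_cens")
    base = cph.baseline_cumulative_hazard_
    base_t = base.index.to_numpy(dtype=float)
    base_h = base.iloc[:, 0].to_numpy(dtype=float)
    eval_t = np.minimum(t, tau)
    # left limit: censoring events exactly at the evaluation time do not count
    idx = np.searchsorted(base_t, eval_t, side="left") - 1
    H0 = np.where(idx >= 0, base_h[np.clip(idx, 0, len(base_h) - 1)], 0.0)
    ph = cph.predict_partial_hazard(df).to_numpy(dtype=float)
    surv = np.exp(-H0 * ph)
    if np.any(surv[at_risk.complete] <= 0):
        raise ValueError("estimated censoring survival reached 0; weights undefined")
    w = np.where(at_risk.complete, 1.0 / np.maximum(surv, 1e-300), np.nan)
    cap = float(np.nanquantile(w, truncation_quantile))
    w = np.minimum(w, cap)
    return IpcwWeights(
        weights=w,
        model_description=f"PH censoring model on {cols}",
        truncation_quantile=truncation_quantile,
        truncated_at=cap,
    )


# ----------------------------------------------------------------------
def _make_learners(kind, seed):
    """Nuisance learner pair (propensity classifier, outcome-regressor factory).

    ``default``: penalized logistic propensity + shallow gradient-boosted
    outcome.  The inverse-weighted score is far more sensitive to propensity
    calibration than to propensity flexibility, and shallow boosted
    classifiers are poorly calibrated; the boosted outcome model keeps the
    flexible fit where flexibility pays.  ``boosting`` boosts both;
    ``linear`` is the fully parametric fallback.
    """
    boosted_clf = HistGradientBoostingClassifier(
        max_depth=3, max_iter=150, learning_rate=0.1, early_stopping=False, random_state=seed
    )
    boosted_reg = lambda: HistGradientBoostingRegressor(  # noqa: E731
        max_depth=3, max_iter=150, learning_rate=0.1, early_stopping=False, random_state=seed
    )
    logit = LogisticRegression(C=100.0, max_iter=3000)
    if kind == "default":
        return logit, boosted_reg
    if kind == "boosting":
        return boosted_clf, boosted_reg
    if kind == "linear":
        return logit, (lambda: Ridge(alpha=1.0))
    raise ValueError("learners must be 'default', 'boosting' or 'linear'")


class _ConstantRegressor:
    """Deliberately uninformative outcome model (misspecification probe)."""

    def fit(self, X, y, **kw):
        self.c_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.c_)


@dataclass
class DmlResults:
    """ATE (and optional subtype GATEs) on the log-time scale."""

    treatment: str
    theta: float
    se: float
    n_complete: int
    scores: np.ndarray  # psi per complete row (cohort order)
    weights: np.ndarray
    subtype_labels: np.ndarray | None = None
    gates: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def time_ratio(self) -> float:
        return float(np.exp(self.theta))

    @property
    def conf_int(self):
        return (self.theta - _Z * self.se, self.theta + _Z * self.se)

    @property
    def time_ratio_conf_int(self):
        lo, hi = self.conf_int
        return (float(np.exp(lo)), float(np.exp(hi)))

    def summary(self) -> str:
        lo, hi = self.time_ratio_conf_int
        lines = [
            f"IPCW-weighted DML-IRM effect of {self.treatment} on log time to MCI",
            "=" * 66,
            f"complete rows: {self.n_complete}",
            f"theta (log-time ATE) = {self.theta:.4f} (se {self.se:.4f})",
            f"geometric-mean time ratio = {self.time_ratio:.3f} (95% CI {lo:.3f}, {hi:.3f})",
        ]
        if self.gates is not None:
            lines += ["", "subtype GATEs (time-ratio scale):", self.gates.to_string()]
        for k, v in self.diagnostics.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def dml_irm_ate(
    at_risk: AtRiskSet,
    weights: IpcwWeights,
    treatment: str,
    confounders=None,
    n_folds=5,
    learners="default",
    seed=0,
    trim=(0.01, 0.99),
    outcome_learner=None,
    propensity_learner=None,
) -> DmlResults:
    """Cross-fitted doubly-robust ATE of ``treatment`` on log observed time.

    Folds are seeded; per fold the propensity and the two outcome
    regressions are fit on the training complete rows and evaluated on the
    held-out complete rows.  Propensities are trimmed to ``trim`` (a
    warning counts trimmed rows).  The score average and its
    influence-function variance use the IPCW weights multiplicatively.
    """
    confounders = list(confounders or default_confounders(treatment))
    data = at_risk.data
    mask = at_risk.complete
    X = data.loc[mask, confounders].to_numpy(dtype=float)
    D = data.loc[mask, treatment].to_numpy(dtype=int)
    Y = at_risk.y[mask]
    w = weights.weights[mask]
    n = len(Y)
    if D.min() == D.max():
        raise ValueError("both treatment arms must be present")

    base_clf, make_reg = _make_learners(learners, seed)
    if propensity_learner is not None:
        base_clf = propensity_learner
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    m_hat = np.empty(n)
    g0 = np.empty(n)
    g1 = np.empty(n)
    fold_losses = []
    for tr, te in folds.split(X):
        d_tr = D[tr]
        if d_tr.min() == d_tr.max():
            raise ValueError(
                "a treatment arm is empty within a training fold; use fewer folds"
            )
        import copy

        clf = copy.deepcopy(base_clf)
        clf.fit(X[tr], d_tr)
        m_hat[te] = clf.predict_proba(X[te])[:, 1]
        if outcome_learner is not None:
            reg1 = copy.deepcopy(outcome_learner)
            reg0 = copy.deepcopy(outcome_learner)
        else:
            reg1, reg0 = make_reg(), make_reg()
        reg1.fit(X[tr][d_tr == 1], Y[tr][d_tr == 1])
        reg0.fit(X[tr][d_tr == 0], Y[tr][d_tr == 0])
        g1[te] = reg1.predict(X[te])
        g0[te] = reg0.predict(X[te])
        resid = np.where(D[te] == 1, Y[te] - g1[te], Y[te] - g0[te])
        fold_losses.append(float(np.mean(resid**2)))

    n_trimmed = int(((m_hat < trim[0]) | (m_hat > trim[1])).sum())
    if n_trimmed:
        warnings.warn(f"{n_trimmed} propensities trimmed to {trim}", stacklevel=2)
    m_hat = np.clip(m_hat, trim[0], trim[1])

    psi = g1 - g0 + D * (Y - g1) / m_hat - (1 - D) * (Y - g0) / (1 - m_hat)
    theta = float(np.sum(w * psi) / np.sum(w))
    se = float(np.sqrt(np.sum(w**2 * (psi - theta) ** 2)) / np.sum(w))
    return DmlResults(
        treatment=treatment,
        theta=theta,
        se=se,
        n_complete=n,
        scores=psi,
        weights=w,
        diagnostics={
            "propensity_range": (float(m_hat.min()), float(m_hat.max())),
            "propensity_trimmed": n_trimmed,
            "outcome_fold_mse": fold_losses,
            "learners": learners,
            "n_folds": n_folds,
        },
    )


def gate_by_subtype(result: DmlResults, subtype_labels, weights=None) -> pd.DataFrame:
    """Group average treatment effects from an existing score vector.

    ``subtype_labels`` aligns with the complete rows of the fit.  A subtype
    with only one treatment arm is flagged non-estimable (NaN estimates)
    rather than failing the others.  The weight-weighted average of the
    GATEs over subtypes equals the ATE (same scores, same weights).
    """
    labels = np.asarray(subtype_labels)
    if labels.shape[0] != result.scores.shape[0]:
        raise ValueError("subtype labels must align with complete rows")
    w = result.weights if weights is None else weights
    rows = []
    for k in np.unique(labels):
        sel = labels == k
        wk, pk = w[sel], result.scores[sel]
        theta_k = float(np.sum(wk * pk) / np.sum(wk))
        se_k = float(np.sqrt(np.sum(wk**2 * (pk - theta_k) ** 2)) / np.sum(wk))
        rows.append(
            {
                "subtype": k,
                "n": int(sel.sum()),
                "theta": theta_k,
                "se": se_k,
                "time_ratio": float(np.exp(theta_k)),
                "tr_ci_low": float(np.exp(theta_k - _Z * se_k)),
                "tr_ci_high": float(np.exp(theta_k + _Z * se_k)),
                "estimable": True,
            }
        )
    out = pd.DataFrame(rows).set_index("subtype")
    return out


def time_ratio(theta, se):
    """Exponentiate a log-time effect: (exp(theta), 95% CI)."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return float(np.exp(theta)), (float(np.exp(theta - _Z * se)), float(np.exp(theta + _Z * se)))


# ----------------------------------------------------------------------
class TreatmentEffectModel:
    """End-to-end causal model for one medication class (statsmodels-style).

    Wraps at-risk definition, IPCW estimation, the cross-fitted IRM fit and
    subtype GATEs behind a single ``fit``.

    Parameters
    ----------
    cohort : DataFrame with follow-up, treatment flags and confounders.
    treatment : medication column name.
    confounders : override of :func:`default_confounders`.
    subtype_col : column with subtype labels for GATEs (optional).
    tau : at-risk cutoff in months.
    """

    def __init__(
        self,
        cohort,
        treatment,
        confounders=None,
        subtype_col=None,
        tau=48.0,
        learners="default",
        n_folds=5,
        truncation_quantile=0.99,
    ):
        if treatment not in cohort.columns:
            raise ValueError(f"treatment column {treatment!r} not in cohort")
        self.cohort = cohort
        self.treatment = treatment
        self.confounders = list(confounders or default_confounders(treatment))
        self.subtype_col = subtype_col
        self.tau = tau
        self.learners = learners
        self.n_folds = n_folds
        self.truncation_quantile = truncation_quantile

    def fit(self, seed=0, **dml_kwargs) -> DmlResults:
        at_risk = define_at_risk(self.cohort, self.tau)
        ipcw = fit_censoring_weights(
            self.cohort,
            self.tau,
            covariates=self.confounders,
            treatment=self.treatment,
            truncation_quantile=self.truncation_quantile,
        )
        res = dml_irm_ate(
            at_risk,
            ipcw,
            self.treatment,
            confounders=self.confounders,
            n_folds=self.n_folds,
            learners=self.learners,
            seed=seed,
            **dml_kwargs,
        )
        if self.subtype_col is not None:
            labels = self.cohort.loc[at_risk.complete, self.subtype_col].to_numpy()
            res.subtype_labels = labels
            res.gates = gate_by_subtype(res, labels)
        res.diagnostics["ipcw"] = ipcw.model_description
        res.diagnostics["ipcw_truncated_at"] = ipcw.truncated_at
        return res
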