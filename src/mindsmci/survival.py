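"""Subtype-specific incident-MCI risk: Kaplan–Meier and Cox models.

Two Cox presets mirror the two reported model shapes:

* ``main_effects`` — subtype (reference: subtype 1) + demographics +
  medication flags; the shape behind the headline subtype hazard ratios.
* ``interactions`` — the same terms plus subtype x medication-class
  interaction blocks.

Age enters per decade (a per-year coding makes the reported age effect
implausible); this is configurable via ``CoxSpec.age_per_decade``.
Estimation delegates to lifelines (Efron tie handling, Wald intervals);
this module owns the model specification, design-matrix construction and
the ordered hazard-ratio table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import ConvergenceError

__all__ = [
    "CoxSpec",
    "CoxResults",
    "KmCurve",
    "km_estimate",
    "SubtypeCoxModel",
    "cox_fit",
    "hr_table",
    "main_effects_spec",
    "interactions_spec",
]


@dataclass
class KmCurve:
    """Product-limit survival curve for one group."""

    group: object
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(times, events, groups=None):
    """Kaplan–Meier curves per group (ties decrement simultaneously).

    Returns a dict group -> :class:`KmCurve`; with ``groups=None`` a single
    curve keyed ``"all"``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    if groups is None:
        groups = np.zeros(len(times))
        labels = {0.0: "all"}
    else:
        groups = np.asarray(groups)
        labels = {g: g for g in pd.unique(groups)}
    out = {}
    for g, label in labels.items():
        mask = groups == g
        if not mask.any():
            raise ValueError(f"empty group: {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        grid = kmf.event_table.index.values.astype(float)
        surv = kmf.survival_function_at_times(grid).values
        out[label] = KmCurve(
            group=label,
            times=grid,
            survival=np.asarray(surv, dtype=float),
            at_risk=kmf.event_table["at_risk"].values,
        )
    return out


# ----------------------------------------------------------------------
@dataclass
class CoxSpec:
    """Specification of a proportional-hazards model on the analytic cohort."""

    time_col: str = "observed_time_months"
    event_col: str = "event_indicator"
    subtype_col: str = "true_subtype"
    demographics: list = field(
        default_factory=lambda: [
            "age",
            "sex_male",
            "race_white",
            "ethnicity_hispanic",
            "education_college",
        ]
    )
    medications: list = field(
        default_factory=lambda: ["antihypertensive", "nonglp_antidiabetic", "glp_class"]
    )
    interaction_pairs: list = field(default_factory=list)  # [(subtype_col, med_col), ...]
    subtype_reference: int = 1
    age_per_decade: bool = True
    age_center: float = 65.0

    def validate(self, cohort: pd.DataFrame):
        needed = (
            [self.time_col, self.event_col, self.subtype_col]
            + self.demographics
            + self.medications
        )
        missing = [c for c in needed if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort is missing columns: {missing}")
        if self.subtype_reference not in set(cohort[self.subtype_col]):
            raise ValueError(
                f"reference level {self.subtype_reference} absent from {self.subtype_col}"
            )


def main_effects_spec(**overrides) -> CoxSpec:
    """Subtype + demographics + medication main effects."""
    return CoxSpec(**overrides)


def interactions_spec(**overrides) -> CoxSpec:
    """Main effects plus subtype x medication interaction blocks."""
    spec = CoxSpec(**overrides)
    spec.interaction_pairs = [("subtype", med) for med in spec.medications]
    return spec


class SubtypeCoxModel:
    """Cox proportional-hazards model of time to MCI (statsmodels-style).

    Builds the design matrix from a :class:`CoxSpec` (subtype dummies
    against the reference level, age per decade and centered, interaction
    columns labelled ``subtype_k * med``) and fits the partial likelihood
    with Efron tie handling via lifelines.
    """

    def __init__(self, cohort: pd.DataFrame, spec: CoxSpec | None = None):
        self.spec = spec or main_effects_spec()
        self.spec.validate(cohort)
        self.cohort = cohort
        self.design, self.term_blocks = self._build_design(cohort)

    def _build_design(self, cohort):
        spec = self.spec
        df = pd.DataFrame(index=cohort.index)
        blocks = {}
        subtype_terms = []
        levels = sorted(set(cohort[spec.subtype_col]))
        for lvl in levels:
            if lvl == spec.subtype_reference:
                continue
            col = f"subtype_{lvl}"
            df[col] = (cohort[spec.subtype_col] == lvl).astype(float)
            subtype_terms.append(col)
        blocks["subtype"] = subtype_terms
        demo_terms = []
        for c in spec.demographics:
            if c == "age":
                scale = 10.0 if spec.age_per_decade else 1.0
                df["age"] = (cohort["age"] - spec.age_center) / scale
            else:
                df[c] = cohort[c].astype(float)
            demo_terms.append(c)
        blocks["demographics"] = demo_terms
        med_terms = []
        for c in spec.medications:
            df[c] = cohort[c].astype(float)
            med_terms.append(c)
        blocks["medications"] = med_terms
        inter_terms = []
        for _, med in spec.interaction_pairs:
            for lvl in levels:
                if lvl == spec.subtype_reference:
                    continue
                col = f"subtype_{lvl} * {med}"
                df[col] = df[f"subtype_{lvl}"] * df[med]
                inter_terms.append(col)
        blocks["interactions"] = inter_terms
        df[spec.time_col] = cohort[spec.time_col].astype(float)
        df[spec.event_col] = cohort[spec.event_col].astype(int)
        return df, blocks

    def fit(self) -> "CoxResults":
        spec = self.spec
        events_by_level = self.cohort.groupby(self.cohort[spec.subtype_col])[
            spec.event_col
        ].sum()
        if (events_by_level > 0).sum() < 2:
            raise ValueError("events present in fewer than two subtype levels")
        cph = CoxPHFitter()
        try:
            cph.fit(self.design, duration_col=spec.time_col, event_col=spec.event_col)
        except (ConvergenceError, np.linalg.LinAlgError) as err:
            raise RuntimeError(
                "Cox partial-likelihood fit failed to converge; check for "
                f"complete separation or collinear terms ({err})"
            ) from err
        return CoxResults(self, cph)


class CoxResults:
    """Hazard ratios, Wald intervals and p-values per design term."""

    def __init__(self, model: SubtypeCoxModel, fitter: CoxPHFitter):
        self.model = model
        self.fitter = fitter
        s = fitter.summary
        self.table = pd.DataFrame(
            {
                "coef": s["coef"],
                "hr": s["exp(coef)"],
                "ci_low": np.exp(s["coef"] - 1.959964 * s["se(coef)"]),
                "ci_high": np.exp(s["coef"] + 1.959964 * s["se(coef)"]),
                "p": s["p"],
            }
        )
        self.log_likelihood = float(fitter.log_likelihood_)

    def hazard_ratio(self, term):
        return float(self.table.loc[term, "hr"])

    def confidence_interval(self, term):
        row = self.table.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def subtype_hazard_ratios(self) -> pd.DataFrame:
        terms = self.model.term_blocks["subtype"]
        return self.table.loc[terms]

    def summary(self) -> str:
        lines = [
            "Cox proportional-hazards fit (Efron ties)",
            "=" * 60,
            f"n = {len(self.model.design)}, events = {int(self.model.design[self.model.spec.event_col].sum())}",
            f"partial log-likelihood = {self.log_likelihood:.1f}",
            "",
            hr_table(self).to_string(index=False),
        ]
        return "\n".join(lines)


def cox_fit(cohort, spec: CoxSpec | None = None) -> CoxResults:
    """Fit a :class:`SubtypeCoxModel` in one call."""
    return SubtypeCoxModel(cohort, spec).fit()


def hr_table(result: CoxResults) -> pd.DataFrame:
    """Ordered hazard-ratio table: subtype block, demographics, medications,
    interaction blocks; reference rows marked with dashes."""
    model = result.model
    spec = model.spec
    n_by_level = model.cohort.groupby(model.cohort[spec.subtype_col]).size()
    rows = [
        {
            "block": "subtype",
            "term": f"subtype_{spec.subtype_reference} (ref)",
            "n": int(n_by_level.get(spec.subtype_reference, 0)),
            "hr": "—",
            "95% CI": "—",
            "p": "",
        }
    ]
    def _fmt(term, block, n=None):
        r = result.table.loc[term]
        return {
            "block": block,
            "term": term,
            "n": n if n is not None else len(model.cohort),
            "hr": f"{r['hr']:.2f}",
            "95% CI": f"{r['ci_low']:.2f}, {r['ci_high']:.2f}",
            "p": f"{r['p']:.3g}",
        }

    for term in model.term_blocks["subtype"]:
        lvl = int(term.split("_")[1])
        rows.append(_fmt(term, "subtype", int(n_by_level.get(lvl, 0))))
    for term in model.term_blocks["demographics"]:
        rows.append(_fmt(term, "demographics"))
    for term in model.term_blocks["medications"]:
        n_users = int(model.cohort[term].sum())
        rows.append(_fmt(term, "medications", n_users))
    for term in model.term_blocks["interactions"]:
        rows.append(_fmt(term, "interactions"))
    return pd.DataFrame(rows)
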