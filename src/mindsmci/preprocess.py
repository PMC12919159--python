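"""Raw-record preprocessing into the analytic cohort.

Covers the cohort-construction rules of the analysis: AUDIT-C alcohol
scoring with sex-specific misuse thresholds, medication-class ascertainment
in the year before baseline, exclusion of subjects with a baseline cognitive
function finding (a parent concept plus all its descendants in a flat
concept-ancestry table), the age >= 50 / complete-modality eligibility
filter, and orientation + z-scoring of the continuous SDOH block.

Raw inputs are plain CSV tables:

* prescriptions: ``subject_id, drug_class, prescription_date``
* conditions:    ``subject_id, concept_id, condition_date``
* ancestry:      ``ancestor_concept_id, descendant_concept_id``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS, TREATMENT_COLUMNS

__all__ = [
    "COGNITIVE_FINDING_CONCEPT",
    "audit_c_score",
    "alcohol_misuse_flag",
    "medication_user_flags",
    "exclude_baseline_cognitive",
    "eligibility_filter",
    "standardize_continuous",
    "StandardizationParams",
    "AttritionReport",
]

#: SNOMED "Cognitive function finding" parent concept in the OMOP vocabulary.
COGNITIVE_FINDING_CONCEPT = 4162723

VALID_DRUG_CLASSES = set(TREATMENT_COLUMNS)


def audit_c_score(frequency_item, quantity_item, binge_item):
    """AUDIT-C total (0-12): sum of three items each scored 0-4.

    Items: drinking frequency, typical quantity per occasion, and frequency
    of binge drinking (6+ drinks on one occasion).
    """
    items = (frequency_item, quantity_item, binge_item)
    arrs = [np.asarray(x) for x in items]
    for name, a in zip(("frequency_item", "quantity_item", "binge_item"), arrs):
        if not np.issubdtype(a.dtype, np.integer):
            if not np.all(np.equal(np.mod(a, 1), 0)):
                raise ValueError(f"{name} must be integer-valued")
            a = a.astype(int)
        if np.any((a < 0) | (a > 4)):
            raise ValueError(f"{name} out of range 0..4")
    total = arrs[0] + arrs[1] + arrs[2]
    return int(total) if np.isscalar(frequency_item) else total.astype(int)


def alcohol_misuse_flag(score, sex):
    """Sex-specific misuse flag: score >= 3 for women, >= 4 for men."""
    score_a = np.asarray(score)
    sex_a = np.asarray(sex, dtype=object)
    if np.any((score_a < 0) | (score_a > 12)):
        raise ValueError("AUDIT-C score out of range 0..12")
    known = {"female", "male"}
    bad = set(np.unique(sex_a)) - known
    if bad:
        raise ValueError(f"unknown sex categories {sorted(map(str, bad))}; expected {sorted(known)}")
    thresh = np.where(sex_a == "female", 3, 4)
    flag = (score_a >= thresh).astype(int)
    return int(flag) if np.isscalar(score) else flag


def medication_user_flags(prescriptions, baseline_dates, window_days=365):
    """Per-subject medication-class flags from prescription records.

    A subject is a user of a class iff at least one prescription of that
    class falls in the closed window ``[baseline - window_days, baseline]``.

    Parameters
    ----------
    prescriptions : DataFrame with columns subject_id, drug_class,
        prescription_date (ISO-8601).
    baseline_dates : Series or dict mapping subject_id -> baseline date.

    Returns
    -------
    DataFrame indexed by subject_id with one 0/1 column per drug class.
    """
    rx = prescriptions.copy()
    bad = set(rx["drug_class"].unique()) - VALID_DRUG_CLASSES
    if bad:
        raise ValueError(
            f"unknown drug_class {sorted(bad)}; valid labels: {sorted(VALID_DRUG_CLASSES)}"
        )
    base = pd.Series(baseline_dates)
    base = pd.to_datetime(base)
    rx["prescription_date"] = pd.to_datetime(rx["prescription_date"])
    rx["baseline"] = rx["subject_id"].map(base)
    delta = (rx["baseline"] - rx["prescription_date"]).dt.days
    in_window = (delta >= 0) & (delta <= window_days)
    flags = pd.DataFrame(0, index=base.index, columns=TREATMENT_COLUMNS, dtype=int)
    hits = rx.loc[in_window].groupby(["subject_id", "drug_class"]).size().unstack(fill_value=0)
    for cls in hits.columns:
        flags.loc[hits.index, cls] = (hits[cls] > 0).astype(int)
    flags.index.name = "subject_id"
    return flags


def exclude_baseline_cognitive(
    conditions,
    ancestry,
    baseline_dates,
    parent_concept=COGNITIVE_FINDING_CONCEPT,
):
    """Subject ids with a cognitive function finding on or before baseline.

    A finding is any condition record whose concept is the parent concept or
    one of its descendants in the (flat, precomputed) ancestry table.
    Records dated after baseline do not exclude.
    """
    if ancestry is None or len(ancestry) == 0:
        raise ValueError("concept ancestry table is required")
    desc = set(
        ancestry.loc[
            ancestry["ancestor_concept_id"] == parent_concept, "descendant_concept_id"
        ].astype(int)
    )
    desc.add(int(parent_concept))
    base = pd.to_datetime(pd.Series(baseline_dates))
    cond = conditions.copy()
    cond["condition_date"] = pd.to_datetime(cond["condition_date"])
    cond["baseline"] = cond["subject_id"].map(base)
    mask = cond["concept_id"].isin(desc) & (cond["condition_date"] <= cond["baseline"])
    return set(cond.loc[mask, "subject_id"])


@dataclass
class AttritionReport:
    """Counts removed at each cohort-derivation step (flow-diagram analogue)."""

    initial: int = 0
    removed_age: int = 0
    removed_missing_modality: int = 0
    removed_cognitive: int = 0
    final: int = 0
    steps: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def eligibility_filter(
    cohort,
    min_age=50,
    require_complete_modalities=True,
    excluded_ids=None,
    binary_cols=BINARY_COLUMNS,
    continuous_cols=CONTINUOUS_COLUMNS,
):
    """Apply the eligibility rules and report attrition.

    Retains rows with age >= ``min_age``, (optionally) at least one
    non-missing cell in each modality block, and subject_id not in
    ``excluded_ids`` (e.g. baseline cognitive findings).  Filters commute:
    retention is the intersection of the three criteria.

    Returns ``(filtered_cohort, AttritionReport)``.
    """
    report = AttritionReport(initial=len(cohort))
    keep = cohort["age"] >= min_age
    report.removed_age = int((~keep).sum())
    if require_complete_modalities:
        bin_present = [c for c in binary_cols if c in cohort.columns]
        cont_present = [c for c in continuous_cols if c in cohort.columns]
        complete = (
            cohort[bin_present].notna().any(axis=1)
            & cohort[cont_present].notna().any(axis=1)
        )
        report.removed_missing_modality = int((keep & ~complete).sum())
        keep &= complete
    if excluded_ids:
        not_cog = ~cohort["subject_id"].isin(excluded_ids)
        report.removed_cognitive = int((keep & ~not_cog).sum())
        keep &= not_cog
    out = cohort.loc[keep].reset_index(drop=True)
    report.final = len(out)
    report.steps = {
        "age": report.removed_age,
        "missing_modality": report.removed_missing_modality,
        "baseline_cognitive": report.removed_cognitive,
    }
    return out, report


@dataclass
class StandardizationParams:
    """Per-column mean/sd and orientation sign, for exact inversion."""

    columns: list
    mean: np.ndarray
    sd: np.ndarray
    sign: np.ndarray

    def inverse(self, standardized: pd.DataFrame) -> pd.DataFrame:
        raw = standardized[self.columns] * self.sd + self.mean
        return raw * self.sign


def standardize_continuous(cohort, columns=CONTINUOUS_COLUMNS, orientation=None):
    """Orient then z-score the continuous block.

    ``orientation`` maps column -> +1 (already higher = worse) or -1 (higher
    = better; flipped before scoring).  Item-level missingness is mean-imputed
    (0 after standardization); whole-block missingness is an eligibility
    matter handled upstream.

    Returns ``(cohort_with_standardized_columns, StandardizationParams)``.
    """
    out = cohort.copy()
    orientation = orientation or {}
    signs, means, sds = [], [], []
    for col in columns:
        sign = float(orientation.get(col, 1))
        vals = out[col].astype(float) * sign
        mu = vals.mean()
        sd = vals.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero-variance continuous column: {col}")
        z = (vals - mu) / sd
        out[col] = z.fillna(0.0)
        signs.append(sign)
        means.append(mu)
        sds.append(sd)
    params = StandardizationParams(
        columns=list(columns),
        mean=np.asarray(means),
        sd=np.asarray(sds),
        sign=np.asarray(signs),
    )
    return out, params
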