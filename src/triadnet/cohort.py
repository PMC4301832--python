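"""Cohort construction from quarterly ambulatory claims.

Pipeline: ICD-10 codes are mapped to chronic diagnosis groups, a diagnosis
counts for a patient only if coded in at least ``min_quarters`` distinct
calendar quarters of the year (screens out transitory or accidental codes),
and the analysis cohort is restricted to multimorbid patients, i.e. those with
at least ``min_conditions`` chronic conditions. Prevalence is always the
column mean over one gender's multimorbid cohort — analyses never pool
genders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .groups import DiagnosisGroup, default_groups, validate_groups

logger = logging.getLogger(__name__)

CLAIMS_COLUMNS = ["patient_id", "gender", "age", "quarter", "icd10"]


class EmptyCohortError(RuntimeError):
    """Raised when filtering leaves no patients to analyse."""


@dataclass
class ConditionMatrix:
    """Patients × diagnosis-groups binary presence matrix with demographics.

    ``data`` is a 0/1 integer frame indexed by patient id with one column per
    group; ``meta`` carries gender and age per patient; ``stage`` records how
    far the cohort filters have been applied (raw → persistent → multimorbid).
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("condition matrix values must be 0/1")
        self.meta = self.meta.loc[self.data.index]

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def group_ids(self) -> list[str]:
        return list(self.data.columns)

    def for_gender(self, gender: str) -> "ConditionMatrix":
        keep = self.meta.index[self.meta["gender"] == gender]
        return replace(self, data=self.data.loc[keep], meta=self.meta.loc[keep])

    def condition_counts(self) -> pd.Series:
        return self.data.sum(axis=1)

    def summary(self) -> dict:
        """Cohort description: counts, age and condition-count moments by gender."""
        out: dict = {"n_patients": int(self.n_patients), "stage": self.stage, "by_gender": {}}
        for gender, meta in self.meta.groupby("gender"):
            counts = self.data.loc[meta.index].sum(axis=1)
            out["by_gender"][gender] = {
                "n": int(len(meta)),
                "share": float(len(meta) / max(self.n_patients, 1)),
                "age_mean": float(meta["age"].mean()),
                "age_sd": float(meta["age"].std(ddof=1)) if len(meta) > 1 else 0.0,
                "conditions_mean": float(counts.mean()),
                "conditions_sd": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
            }
        return out


def validate_claims(claims: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLAIMS_COLUMNS if c not in claims.columns]
    if missing:
        raise ValueError(f"claims table missing columns {missing}")
    if not claims["quarter"].isin([1, 2, 3, 4]).all():
        raise ValueError("quarter must be in {1,2,3,4}")
    if not claims["gender"].isin(["F", "M"]).all():
        raise ValueError("gender must be 'F' or 'M'")
    return claims


def map_icd_to_groups(
    claims: pd.DataFrame, groups: list[DiagnosisGroup] | None = None
) -> pd.DataFrame:
    """Annotate claims rows with ``group_id``; rows with unmapped codes are dropped.

    The number of dropped rows is logged and stored in ``.attrs['n_unmapped']``.
    """
    groups = default_groups() if groups is None else groups
    validate_groups(groups)
    claims = validate_claims(claims)

    # longest-prefix table; non-overlap is guaranteed by validate_groups
    prefixes = sorted(
        ((p, g.group_id) for g in groups for p in g.icd10_patterns),
        key=lambda t: -len(t[0]),
    )
    codes = claims["icd10"].astype(str).str.strip().str.upper()
    group_id = pd.Series(pd.NA, index=claims.index, dtype="object")
    for pat, gid in prefixes:
        unassigned = group_id.isna()
        group_id.loc[unassigned & codes[unassigned].str.startswith(pat)] = gid

    mapped = claims.assign(group_id=group_id)
    n_unmapped = int(group_id.isna().sum())
    if n_unmapped:
        logger.info("dropped %d claims with ICD codes outside the group list", n_unmapped)
    mapped = mapped.dropna(subset=["group_id"]).copy()
    mapped.attrs["n_unmapped"] = n_unmapped
    return mapped


def apply_persistence_rule(
    claims: pd.DataFrame,
    min_quarters: int = 3,
    groups: list[DiagnosisGroup] | None = None,
) -> ConditionMatrix:
    """Patient has a condition iff its group is coded in ≥ min_quarters distinct quarters.

    Duplicate codes within one quarter count once: the rule counts calendar
    periods, not claims.
    """
    if min_quarters not in (1, 2, 3, 4):
        raise ValueError(f"min_quarters must be in 1..4, got {min_quarters}")
    if "group_id" not in claims.columns:
        claims = map_icd_to_groups(claims, groups)

    if groups is not None:
        group_ids = [g.group_id for g in groups]
    else:  # already-annotated claims: keep the groups they were mapped with
        group_ids = sorted(claims["group_id"].unique())
    meta = (
        claims.groupby("patient_id")
        .agg(gender=("gender", "first"), age=("age", "first"))
        .astype({"age": int})
    )
    nq = (
        claims.drop_duplicates(["patient_id", "group_id", "quarter"])
        .groupby(["patient_id", "group_id"])
        .size()
    )
    present = nq[nq >= min_quarters].reset_index(name="nq")
    data = pd.DataFrame(0, index=meta.index, columns=pd.Index(group_ids, name="group_id"))
    if len(present):
        wide = pd.crosstab(present["patient_id"], present["group_id"])
        data.loc[wide.index, wide.columns] = wide.to_numpy()
    return ConditionMatrix(data=data.astype(int), meta=meta, stage="persistent")


def filter_multimorbid(matrix: ConditionMatrix, min_conditions: int = 3) -> ConditionMatrix:
    """Retain patients with ≥ min_conditions chronic conditions (the multimorbid cohort)."""
    if min_conditions < 0:
        raise ValueError("min_conditions must be non-negative")
    keep = matrix.data.index[matrix.condition_counts() >= min_conditions]
    retained = len(keep) / matrix.n_patients if matrix.n_patients else 0.0
    logger.info(
        "multimorbidity filter (≥%d conditions): retained %d/%d patients (%.1f%%)",
        min_conditions, len(keep), matrix.n_patients, 100 * retained,
    )
    if not len(keep):
        logger.warning("multimorbidity filter left an empty cohort")
    return ConditionMatrix(
        data=matrix.data.loc[keep], meta=matrix.meta.loc[keep], stage="multimorbid"
    )


def compute_prevalence(matrix: ConditionMatrix, gender: str | None = None) -> pd.Series:
    """Marginal prevalence per group: column mean over the (gendered) cohort.

    The denominator (cohort size) is stored in ``.attrs['n']``.
    """
    sub = matrix if gender is None else matrix.for_gender(gender)
    if sub.n_patients == 0:
        raise EmptyCohortError(f"no patients in cohort (gender={gender!r})")
    prev = sub.data.mean(axis=0)
    prev.name = "prevalence"
    prev.attrs["n"] = sub.n_patients
    prev.attrs["gender"] = gender
    return prev


class CohortBuilder(BaseEstimator, TransformerMixin):
    """Transformer from long-format quarterly claims to the multimorbid cohort matrix.

    Parameters
    ----------
    groups : list of DiagnosisGroup, optional
        Diagnosis-group mapping; defaults to the packaged 46-group config.
    min_quarters : int, default 3
        Distinct-quarter persistence threshold.
    min_conditions : int, default 3
        Multimorbidity threshold (number of chronic conditions).

    After ``transform``, ``funnel_`` holds the patient counts at each filter
    stage and ``n_unmapped_`` the number of dropped claims rows.
    """

    def __init__(self, groups=None, min_quarters: int = 3, min_conditions: int = 3):
        self.groups = groups
        self.min_quarters = min_quarters
        self.min_conditions = min_conditions

    def fit(self, X: pd.DataFrame, y=None):
        validate_groups(self.groups if self.groups is not None else default_groups())
        validate_claims(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> ConditionMatrix:
        mapped = map_icd_to_groups(X, self.groups)
        self.n_unmapped_ = mapped.attrs["n_unmapped"]
        persistent = apply_persistence_rule(mapped, self.min_quarters, self.groups)
        cohort = filter_multimorbid(persistent, self.min_conditions)
        self.funnel_ = {
            "claims_rows": int(len(X)),
            "mapped_rows": int(len(mapped)),
            "patients_with_claims": int(persistent.n_patients),
            "multimorbid_patients": int(cohort.n_patients),
        }
        return cohort
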