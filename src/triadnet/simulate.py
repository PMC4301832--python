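"""Synthetic quarterly claims for a gendered elderly cohort.

The generator uses a latent Gaussian threshold model: each patient draws a
multivariate normal vector with a configured correlation matrix, and condition
j is present iff its latent value exceeds the probit quantile matching the
gender-specific target prevalence. This is exactly the model under which the
tetrachoric correlation is a consistent estimator, so the downstream cluster
stage has a well-defined parameter-recovery target. Correlation structure is
specified as two overlapping blocks (cardio-metabolic, anxiety/depression/
somatoform/pain) with "bridge" conditions loading on both — bridges are what
make the planted clusters overlap.

True conditions are then unrolled into quarterly claims: a present condition
is coded in ≥3 of 4 quarters with probability ``persistence_prob`` (otherwise
in ≤2 quarters, and so lost to the persistence rule), and transient noise
diagnoses lasting 1–2 quarters are added at ``noise_rate`` per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ConditionMatrix
from .groups import DiagnosisGroup, default_groups

#: multimorbid 65+ cohort demographics: (mean, sd) of age by gender and the
#: female share of the cohort.
AGE_BY_GENDER = {"F": (73.3, 6.8), "M": (72.2, 5.9)}
FEMALE_SHARE = 0.442

#: planted block memberships of the default 46-group config. Obesity and
#: joint arthrosis act as bridges between the metabolic and pain blocks,
#: mirroring the metabolic-syndrome ↔ musculoskeletal overlap.
DEFAULT_BLOCKS = {
    "cardiometabolic": [
        "hypertension", "lipid_metabolism_disorders", "diabetes_mellitus",
        "chronic_ischemic_heart_disease", "hyperuricemia_gout",
        "cardiac_arrhythmias", "atherosclerosis_paod", "liver_diseases",
        "cardiac_insufficiency", "cerebral_ischemia_chronic_stroke",
        "neuropathies", "renal_insufficiency", "cardiac_valve_disorders",
    ],
    "ads_pain": [
        "chronic_low_back_pain", "lower_limb_varicosis", "prostatic_hyperplasia",
        "asthma_copd", "depression", "chronic_gastritis_gerd", "osteoporosis",
        "gynaecological_problems", "allergies", "insomnia",
        "intestinal_diverticulosis", "hemorrhoids", "somatoform_disorders",
        "severe_hearing_loss", "dizziness", "anxiety", "sexual_dysfunction",
    ],
}
DEFAULT_BRIDGES = ["obesity", "joint_arthrosis"]


def block_correlation(
    group_ids: list[str],
    blocks: dict[str, list[str]],
    bridges: list[str] | None = None,
    within: float = 0.5,
) -> pd.DataFrame:
    """Unit-diagonal PSD correlation with planted overlapping blocks.

    Built as ``R = Λ Λᵀ + diag(1 − ‖Λ_row‖²)`` from a two-column loading
    matrix: block members load ``sqrt(within)`` on their block's factor
    (within-block correlation = ``within``), bridges load ``sqrt(within/2)``
    on every factor, and unlisted groups are independent. The construction is
    PSD for any 0 ≤ within < 1.
    """
    if not 0 <= within < 1:
        raise ValueError("within-block correlation must be in [0, 1)")
    bridges = bridges or []
    lam = np.zeros((len(group_ids), len(blocks)))
    block_ix = {name: k for k, name in enumerate(blocks)}
    for name, members in blocks.items():
        for gid in members:
            lam[group_ids.index(gid), block_ix[name]] = np.sqrt(within)
    for gid in bridges:
        lam[group_ids.index(gid), :] = np.sqrt(within / len(blocks))
    corr = lam @ lam.T
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=group_ids, columns=group_ids)


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic claims generator."""

    groups: list[DiagnosisGroup]
    n_patients: int = 1000
    gender_mix: float = FEMALE_SHARE
    age_by_gender: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(AGE_BY_GENDER)
    )
    latent_correlation: pd.DataFrame | None = None  # None → independence
    persistence_prob: float = 0.9
    noise_rate: float = 1.0
    seed: int = 20061

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    def prevalence(self, gender: str) -> np.ndarray:
        return np.array([g.prevalence(gender) for g in self.groups])

    def correlation_matrix(self) -> np.ndarray:
        if self.latent_correlation is None:
            return np.eye(len(self.groups))
        corr = self.latent_correlation.loc[self.group_ids, self.group_ids].to_numpy()
        return corr

    def validate(self) -> "GeneratorConfig":
        if self.n_patients < 1:
            raise ValueError("n_patients must be ≥ 1")
        if not 0 <= self.gender_mix <= 1:
            raise ValueError("gender_mix must be in [0, 1]")
        if not 0 <= self.persistence_prob <= 1:
            raise ValueError("persistence_prob must be in [0, 1]")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be ≥ 0")
        for gender in "FM":
            p = self.prevalence(gender)
            if ((p < 0) | (p >= 1)).any():
                raise ValueError("prevalences must be in [0, 1)")
        for g in self.groups:
            if g.gender_restriction == "female_only" and g.prevalence_male != 0:
                raise ValueError(f"{g.group_id}: female-only group with male prevalence > 0")
            if g.gender_restriction == "male_only" and g.prevalence_female != 0:
                raise ValueError(f"{g.group_id}: male-only group with female prevalence > 0")
        corr = self.correlation_matrix()
        if not np.allclose(corr, corr.T, atol=1e-10) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("latent_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("latent_correlation is not positive semidefinite")
        return self


def build_default_config(scale: int, seed: int = 20061) -> GeneratorConfig:
    """Default study conditions: 46 groups, published prevalences, two planted
    overlapping blocks over the cardio-metabolic and ADS/pain conditions."""
    if scale < 1:
        raise ValueError("scale must be ≥ 1")
    groups = default_groups()
    corr = block_correlation(
        [g.group_id for g in groups], DEFAULT_BLOCKS, DEFAULT_BRIDGES, within=0.5
    )
    return GeneratorConfig(
        groups=groups, n_patients=scale, latent_correlation=corr, seed=seed
    ).validate()


def sample_condition_matrix(config: GeneratorConfig) -> ConditionMatrix:
    """Draw the ground-truth binary condition matrix under the latent model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, len(config.groups)

    gender = np.where(rng.random(n) < config.gender_mix, "F", "M")
    age = np.empty(n)
    for g, (mu, sd) in config.age_by_gender.items():
        mask = gender == g
        age[mask] = rng.normal(mu, sd, mask.sum())
    age = np.clip(np.round(age), 65, 105).astype(int)

    corr = config.correlation_matrix()
    # eigen-based root: tolerant of exactly-singular PSD block structures
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    z = rng.standard_normal((n, p)) @ root.T

    present = np.zeros((n, p), dtype=int)
    for g in "FM":
        mask = gender == g
        with np.errstate(divide="ignore"):
            thresh = stats.norm.ppf(1 - config.prevalence(g))  # p=0 → +inf → absent
        present[mask] = (z[mask] > thresh).astype(int)

    index = pd.Index([f"P{i:06d}" for i in range(n)], name="patient_id")
    data = pd.DataFrame(present, index=index, columns=pd.Index(config.group_ids, name="group_id"))
    meta = pd.DataFrame({"gender": gender, "age": age}, index=index)
    return ConditionMatrix(data=data, meta=meta, stage="raw")


def _draw_icd(rng: np.random.Generator, group: DiagnosisGroup) -> str:
    prefix = group.icd10_patterns[rng.integers(len(group.icd10_patterns))]
    return f"{prefix}.{rng.integers(10)}" if len(prefix) == 3 else f"{prefix}{rng.integers(10)}"


def emit_quarterly_claims(matrix: ConditionMatrix, config: GeneratorConfig) -> pd.DataFrame:
    """Unroll a ground-truth matrix into long-format quarterly claims.

    Sampling order is patient-major, group-minor, so output is reproducible
    for a given config and seed. Noise diagnoses are uniform over the groups
    permitted for the patient's gender and last 1–2 quarters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)  # separate stream from sampling
    by_id = {g.group_id: g for g in config.groups}
    quarters = np.arange(1, 5)
    rows: list[tuple] = []

    missing = set(matrix.data.columns) - set(by_id)
    if missing:
        raise KeyError(f"groups missing from generator mapping: {sorted(missing)}")
    columns = np.array(matrix.data.columns)
    truth_arr = matrix.data.to_numpy().astype(bool)
    genders = matrix.meta["gender"].to_numpy()
    ages = matrix.meta["age"].to_numpy()

    for row, (pid, gender, age) in enumerate(zip(matrix.data.index, genders, ages)):
        age = int(age)
        for gid in columns[truth_arr[row]]:
            persistent = rng.random() < config.persistence_prob
            k = rng.integers(3, 5) if persistent else rng.integers(1, 3)
            qs = rng.choice(quarters, size=k, replace=False)
            code = _draw_icd(rng, by_id[gid])
            rows += [(pid, gender, age, int(q), code) for q in sorted(qs)]
        allowed = [g for g in config.groups if g.allowed_for(gender)]
        for _ in range(rng.poisson(config.noise_rate)):
            g = allowed[rng.integers(len(allowed))]
            qs = rng.choice(quarters, size=rng.integers(1, 3), replace=False)
            code = _draw_icd(rng, g)
            rows += [(pid, gender, age, int(q), code) for q in sorted(qs)]

    return pd.DataFrame(rows, columns=["patient_id", "gender", "age", "quarter", "icd10"])


def simulate_claims(config: GeneratorConfig) -> tuple[pd.DataFrame, ConditionMatrix]:
    """Convenience: sample the ground truth and emit its claims table."""
    truth = sample_condition_matrix(config)
    return emit_quarterly_claims(truth, config), truth
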