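import numpy as np
import pandas as pd
import pytest

from triadnet import (
    DiagnosisGroup,
    GeneratorConfig,
    block_correlation,
    build_default_config,
    sample_condition_matrix,
)
from triadnet.cohort import ConditionMatrix


@pytest.fixture
def toy_groups():
    return [
        DiagnosisGroup("htn", "Hypertension", ("I10",)),
        DiagnosisGroup("dm", "Diabetes", ("E10", "E11")),
        DiagnosisGroup("clbp", "Low back pain", ("M54",)),
        DiagnosisGroup("gyn", "Gynaecological", ("N81",), "female_only"),
    ]


@pytest.fixture
def toy_claims():
    rows = [
        # p1: htn in 3 quarters, dm in 2 → only htn persists
        ("p1", "F", 70, 1, "I10"), ("p1", "F", 70, 2, "I10"), ("p1", "F", 70, 3, "I10"),
        ("p1", "F", 70, 1, "E11"), ("p1", "F", 70, 4, "E11"),
        # p2: clbp coded 5 times but only in quarter 2
        ("p2", "M", 68, 2, "M54.5"), ("p2", "M", 68, 2, "M54.5"), ("p2", "M", 68, 2, "M54.4"),
        ("p2", "M", 68, 2, "M54.5"), ("p2", "M", 68, 2, "M54.5"),
        # p3: three persistent conditions → multimorbid
        *[("p3", "F", 81, q, c) for q in (1, 2, 3, 4) for c in ("I10", "E10", "M54.1")],
        # p4: unmapped code only
        ("p4", "M", 75, 1, "Z99"),
    ]
    return pd.DataFrame(rows, columns=["patient_id", "gender", "age", "quarter", "icd10"])


def make_matrix(values, genders=None, ages=None, columns=None):
    values = np.asarray(values)
    n, p = values.shape
    columns = columns or [f"g{j}" for j in range(p)]
    idx = pd.Index([f"p{i}" for i in range(n)], name="patient_id")
    meta = pd.DataFrame(
        {"gender": genders or ["F"] * n, "age": ages or [70] * n}, index=idx
    )
    return ConditionMatrix(
        data=pd.DataFrame(values, index=idx, columns=columns), meta=meta, stage="multimorbid"
    )


def two_block_config(n_patients=10_000, within=0.5, seed=101):
    """Planted-structure cohort: two 5-condition blocks plus two bridges."""
    block_a = [f"a{i}" for i in range(5)]
    block_b = [f"b{i}" for i in range(5)]
    bridges = ["bridge1", "bridge2"]
    ids = block_a + block_b + bridges
    prev = [0.45, 0.35, 0.25, 0.2, 0.15] * 2 + [0.3, 0.2]
    groups = [
        DiagnosisGroup(g, g, (f"X{i:02d}",), "both", p, p)
        for i, (g, p) in enumerate(zip(ids, prev))
    ]
    corr = block_correlation(ids, {"A": block_a, "B": block_b}, bridges, within=within)
    cfg = GeneratorConfig(
        groups=groups, n_patients=n_patients, latent_correlation=corr, seed=seed,
        persistence_prob=1.0, noise_rate=0.0,
    )
    return cfg.validate(), block_a, block_b, bridges


@pytest.fixture(scope="session")
def planted_cohort():
    cfg, block_a, block_b, bridges = two_block_config()
    return sample_condition_matrix(cfg), block_a, block_b, bridges


@pytest.fixture(scope="session")
def default_cohort_10k():
    cfg = build_default_config(10_000, seed=11)
    return cfg, sample_condition_matrix(cfg)
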