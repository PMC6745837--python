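"""Shared fixtures: hand-built toy cohorts and generated study-scale cohorts."""

import numpy as np
import pandas as pd
import pytest

from actbench import Cohort, GeneratorConfig, generate_cohort, null_config
from actbench.cohort import HOSPITAL_COLUMNS, PATIENT_COLUMNS


def make_patients(rows: list[dict]) -> pd.DataFrame:
    """Patient rows from dicts of overrides on a valid template."""
    template = {
        "patient_id": None,
        "hospital_id": "H1",
        "treated": 1,
        "age_group": "60-69",
        "sex": "F",
        "ses_quintile": "3",
        "charlson": "0",
        "length_of_stay": 8,
        "t_stage": "T3",
        "n_stage": "N1",
        "grade": "well-moderate",
        "lvi": "no",
        "node_harvest": ">=12",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(template)
        rec["patient_id"] = f"P{i+1:03d}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)[PATIENT_COLUMNS]


def make_hospitals(ids, **flags) -> pd.DataFrame:
    df = pd.DataFrame({"hospital_id": list(ids)})
    for col in ("teaching", "cancer_centre", "medonc_onsite"):
        df[col] = flags.get(col, [0] * len(df))
    return df[HOSPITAL_COLUMNS]


def counts_cohort(spec: list[tuple[str, int, int]], flags: dict | None = None) -> Cohort:
    """Cohort from (hospital_id, n, k) triples with template covariates."""
    rows = []
    for hid, n, k in spec:
        for j in range(n):
            rows.append({"hospital_id": hid, "treated": 1 if j < k else 0})
    patients = make_patients(rows)
    hospitals = make_hospitals([h for h, _, _ in spec], **(flags or {}))
    return Cohort(patients, hospitals)


@pytest.fixture
def tiny_cohort() -> Cohort:
    patients = make_patients(
        [
            {"hospital_id": "H1", "treated": 1},
            {"hospital_id": "H1", "treated": 0, "age_group": "80+"},
            {"hospital_id": "H2", "treated": 1, "sex": "M"},
        ]
    )
    hospitals = make_hospitals(["H1", "H2"], teaching=[1, 0])
    return Cohort(patients, hospitals)


@pytest.fixture(scope="session")
def study_cohort():
    """Default study-like cohort (72 hospitals, 2801 patients, sd = 0)."""
    cohort, truth = generate_cohort(GeneratorConfig(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Pure-chance cohort: no covariate effects, no hospital effects."""
    cohort, truth = generate_cohort(null_config(seed=7))
    return cohort, truth
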