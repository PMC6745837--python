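"""Patient-level cohort container with delimited-text I/O and domain validation.

A cohort is one row per resected stage III colon cancer patient: the hospital
where surgery took place, a binary indicator of adjuvant chemotherapy (ACT)
started within 16 weeks of surgery, and the patient- and disease-level
covariates used for case-mix adjustment. Hospital attributes (teaching status,
comprehensive-cancer-centre status, on-site medical oncology) live in a
companion table keyed by ``hospital_id``.

Unknown/NA levels (SES unknown, LVI NA, grade unstated, node-harvest unknown)
are first-class category levels rather than missing data, so denominators are
preserved everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReferentialIntegrityError, SchemaError, ValidationError

AGE_LEVELS = ["20-49", "50-59", "60-69", "70-79", "80+"]
SEX_LEVELS = ["M", "F"]
SES_LEVELS = ["1", "2", "3", "4", "5", "unknown"]
CHARLSON_LEVELS = ["0", "1", "2+"]
T_STAGE_LEVELS = ["T<=1", "T2", "T3", "T4"]
N_STAGE_LEVELS = ["N1", "N2"]
GRADE_LEVELS = ["well-moderate", "poor", "unstated"]
LVI_LEVELS = ["yes", "no", "NA"]
NODE_LEVELS = [">=12", "<12", "unknown"]

#: categorical domain of every covariate column
CATEGORY_DOMAINS: dict[str, list[str]] = {
    "age_group": AGE_LEVELS,
    "sex": SEX_LEVELS,
    "ses_quintile": SES_LEVELS,
    "charlson": CHARLSON_LEVELS,
    "t_stage": T_STAGE_LEVELS,
    "n_stage": N_STAGE_LEVELS,
    "grade": GRADE_LEVELS,
    "lvi": LVI_LEVELS,
    "node_harvest": NODE_LEVELS,
}

PATIENT_COLUMNS = [
    "patient_id",
    "hospital_id",
    "treated",
    "age_group",
    "sex",
    "ses_quintile",
    "charlson",
    "length_of_stay",
    "t_stage",
    "n_stage",
    "grade",
    "lvi",
    "node_harvest",
]

HOSPITAL_COLUMNS = ["hospital_id", "teaching", "cancer_centre", "medonc_onsite"]

HOSPITAL_FLAGS = ["teaching", "cancer_centre", "medonc_onsite"]


@dataclass
class PatientRecord:
    """One treated/untreated patient with covariates and hospital assignment."""

    patient_id: str
    hospital_id: str
    treated: int
    age_group: str
    sex: str
    ses_quintile: str
    charlson: str
    length_of_stay: int
    t_stage: str
    n_stage: str
    grade: str
    lvi: str
    node_harvest: str

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in PATIENT_COLUMNS}


@dataclass
class HospitalProfile:
    """Hospital id, system-level flags, and case count (derived from cohort)."""

    hospital_id: str
    teaching: int = 0
    cancer_centre: int = 0
    medonc_onsite: int = 0
    n_cases: int = 0

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in HOSPITAL_COLUMNS}


@dataclass
class Cohort:
    """A validated patient table plus its hospital attribute table.

    ``patients`` has :data:`PATIENT_COLUMNS`; ``hospitals`` has
    :data:`HOSPITAL_COLUMNS` plus a derived ``n_cases`` column. Construction
    validates category domains, flag values and referential integrity.
    """

    patients: pd.DataFrame
    hospitals: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.patients = self.patients.reset_index(drop=True)
        if self.hospitals is None:
            ids = sorted(self.patients["hospital_id"].unique())
            self.hospitals = pd.DataFrame(
                {"hospital_id": ids, "teaching": 0, "cancer_centre": 0, "medonc_onsite": 0}
            )
        self.hospitals = self.hospitals.reset_index(drop=True)
        _validate_patients(self.patients)
        _validate_hospitals(self.hospitals)
        unknown = set(self.patients["hospital_id"]) - set(self.hospitals["hospital_id"])
        if unknown:
            raise ReferentialIntegrityError(
                f"patients reference hospital_id(s) absent from the hospital table: "
                f"{sorted(unknown)}"
            )
        counts = self.patients["hospital_id"].value_counts()
        self.hospitals = self.hospitals.copy()
        self.hospitals["n_cases"] = (
            self.hospitals["hospital_id"].map(counts).fillna(0).astype(int)
        )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_hospitals(self) -> int:
        return len(self.hospitals)

    @property
    def treated_rate(self) -> float:
        """Overall ACT rate, pooled over all patients."""
        return float(self.patients["treated"].mean())

    @classmethod
    def from_records(
        cls,
        patients: list[PatientRecord],
        hospitals: list[HospitalProfile] | None = None,
    ) -> "Cohort":
        pdf = pd.DataFrame([p.to_dict() for p in patients], columns=PATIENT_COLUMNS)
        hdf = None
        if hospitals is not None:
            hdf = pd.DataFrame([h.to_dict() for h in hospitals], columns=HOSPITAL_COLUMNS)
        return cls(pdf, hdf)

    def merged(self) -> pd.DataFrame:
        """Patient table with hospital flags merged on (one row per patient)."""
        return self.patients.merge(self.hospitals, on="hospital_id", how="left")

    def equals(self, other: "Cohort") -> bool:
        a = self.patients.sort_values("patient_id").reset_index(drop=True)
        b = other.patients.sort_values("patient_id").reset_index(drop=True)
        ha = self.hospitals.sort_values("hospital_id").reset_index(drop=True)
        hb = other.hospitals.sort_values("hospital_id").reset_index(drop=True)
        return a.equals(b) and ha.equals(hb)


def _validate_patients(df: pd.DataFrame) -> None:
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"patient table missing column(s): {missing}")
    bad_rows: dict[int, list[str]] = {}

    def _flag(mask: pd.Series, what: str) -> None:
        for idx in df.index[mask]:
            bad_rows.setdefault(int(idx) + 2, []).append(what)  # +2: header + 1-based

    for col, domain in CATEGORY_DOMAINS.items():
        _flag(~df[col].astype(str).isin(domain), f"{col} outside {domain}")
    treated = pd.to_numeric(df["treated"], errors="coerce")
    _flag(~treated.isin([0, 1]), "treated not in {0,1}")
    los = pd.to_numeric(df["length_of_stay"], errors="coerce")
    _flag(los.isna() | (los < 0) | (los != los.round()), "length_of_stay not a non-negative integer")
    _flag(df["hospital_id"].astype(str).str.len() == 0, "empty hospital_id")
    if bad_rows:
        lines = [f"row {r}: {'; '.join(v)}" for r, v in sorted(bad_rows.items())]
        raise ValidationError(
            "invalid patient rows:\n" + "\n".join(lines), rows=sorted(bad_rows)
        )
    dupes = df["patient_id"][df["patient_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate patient_id(s): {sorted(map(str, dupes))}")


def _validate_hospitals(df: pd.DataFrame) -> None:
    missing = [c for c in HOSPITAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"hospital table missing column(s): {missing}")
    for col in HOSPITAL_FLAGS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if not vals.isin([0, 1]).all():
            raise ValidationError(f"hospital flag {col!r} must be binary 0/1")
    dupes = df["hospital_id"][df["hospital_id"].duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"duplicate hospital_id(s): {sorted(map(str, dupes))}")


def _coerce_patient_types(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("patient_id", "hospital_id"):
        df[col] = df[col].astype(str)
    for col in CATEGORY_DOMAINS:
        df[col] = df[col].astype(str)
    df["treated"] = pd.to_numeric(df["treated"]).astype(np.int64)
    df["length_of_stay"] = pd.to_numeric(df["length_of_stay"]).astype(np.int64)
    return df[PATIENT_COLUMNS]


def read_cohort(patient_path: str | Path, hospital_path: str | Path) -> Cohort:
    """Read and validate a cohort from two CSV files.

    Raises :class:`SchemaError` on missing columns, :class:`ValidationError`
    listing offending row numbers on domain violations, and
    :class:`ReferentialIntegrityError` on unresolvable ``hospital_id``.
    """
    patients = pd.read_csv(patient_path, dtype=str, keep_default_na=False)
    hospitals = pd.read_csv(hospital_path, dtype=str, keep_default_na=False)
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise SchemaError(f"{patient_path}: missing column(s) {missing}")
    _validate_patients(patients)  # validate on raw strings for row reporting
    patients = _coerce_patient_types(patients)
    missing_h = [c for c in HOSPITAL_COLUMNS if c not in hospitals.columns]
    if missing_h:
        raise SchemaError(f"{hospital_path}: missing column(s) {missing_h}")
    hospitals = hospitals.copy()
    hospitals["hospital_id"] = hospitals["hospital_id"].astype(str)
    for col in HOSPITAL_FLAGS:
        hospitals[col] = pd.to_numeric(hospitals[col], errors="coerce")
        if not hospitals[col].isin([0, 1]).all():
            raise ValidationError(f"{hospital_path}: flag {col!r} must be binary 0/1")
        hospitals[col] = hospitals[col].astype(np.int64)
    return Cohort(patients, hospitals[HOSPITAL_COLUMNS])


def write_cohort(
    cohort: Cohort, patient_path: str | Path, hospital_path: str | Path
) -> None:
    """Write a cohort to two CSV files that :func:`read_cohort` parses back."""
    cohort.patients[PATIENT_COLUMNS].to_csv(patient_path, index=False)
    cohort.hospitals[HOSPITAL_COLUMNS].to_csv(hospital_path, index=False)
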