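"""Clinical-index feature engineering for EOS cohorts.

Turns raw per-patient rows (etiology plus five measured radiographic
indices) into the six-feature matrix the clustering operates on:

    age (years), major curve Cobb angle (deg), kyphosis (deg),
    levels in the major curve, levels in kyphosis, deformity index.

The deformity index is the ratio of the major Cobb angle to kyphosis;
values above one mean the coronal deformity dominates the sagittal one.
Because the six indices mix years, degrees, counts and a ratio, the
matrix is z-scored per column before clustering and the scaling
parameters are retained so that new patients can be projected into the
same standardized space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ETIOLOGIES = ("congenital", "idiopathic", "neuromuscular", "syndromic")

FEATURE_NAMES = (
    "age_years",
    "cobb_major_deg",
    "kyphosis_deg",
    "levels_cobb",
    "levels_kyphosis",
    "deformity_index",
)

#: exact CSV column names of the patient-table schema
CSV_COLUMNS = (
    "subject_id",
    "etiology",
    "age_years",
    "cobb_major_deg",
    "kyphosis_deg",
    "levels_cobb",
    "levels_kyphosis",
)


@dataclass(frozen=True)
class PatientRecord:
    """One subject: etiology plus the five measured clinical indices.

    Measured fields may be NaN for records read from incomplete rows;
    such records are excluded (with a logged reason) when the feature
    matrix is built.
    """

    subject_id: str
    etiology: str
    age: float
    cobb_major: float
    kyphosis: float
    levels_cobb: float
    levels_kyphosis: float

    def __post_init__(self) -> None:
        if self.etiology not in ETIOLOGIES:
            raise ValueError(
                f"unknown etiology {self.etiology!r}; expected one of {ETIOLOGIES}"
            )
        if not math.isnan(self.age) and not 0.0 <= self.age <= 10.0:
            logger.warning(
                "subject %s: age %.2f outside the EOS range [0, 10]",
                self.subject_id,
                self.age,
            )

    @property
    def is_complete(self) -> bool:
        vals = (self.age, self.cobb_major, self.kyphosis,
                self.levels_cobb, self.levels_kyphosis)
        return all(math.isfinite(v) for v in vals)

    def missing_fields(self) -> list[str]:
        names = ("age", "cobb_major", "kyphosis", "levels_cobb", "levels_kyphosis")
        vals = (self.age, self.cobb_major, self.kyphosis,
                self.levels_cobb, self.levels_kyphosis)
        return [n for n, v in zip(names, vals) if not math.isfinite(v)]


@dataclass(frozen=True)
class Scaling:
    """Per-feature mean/SD of a standardization, kept for reuse.

    SDs use the sample convention (divisor n-1).  Constant columns are
    recorded with SD 1 so the transform stays invertible.
    """

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return values * self.sd + self.mean

    def to_dict(self) -> dict:
        return {"mean": [float(x) for x in self.mean],
                "sd": [float(x) for x in self.sd]}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaling":
        return cls(mean=np.asarray(d["mean"], dtype=float),
                   sd=np.asarray(d["sd"], dtype=float))


@dataclass(frozen=True)
class FeatureMatrix:
    """n_subjects x 6 feature matrix for one etiology.

    ``scaling`` is None for a raw (unstandardized) matrix and holds the
    z-scoring parameters after :func:`standardize`.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    etiology: str
    scaling: Scaling | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"feature matrix must have {len(FEATURE_NAMES)} columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids must align with matrix rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def is_standardized(self) -> bool:
        return self.scaling is not None


def compute_deformity_index(
    cobb_major: float, kyphosis: float, kyphosis_floor: float = 1.0
) -> float:
    """Ratio of the major Cobb angle to kyphosis.

    Kyphosis is floored at ``kyphosis_floor`` degrees so hypokyphotic or
    lordotic sagittal profiles (kyphosis near or below zero) yield a
    finite, positive index; non-positive kyphosis triggers a warning.
    """
    if cobb_major <= 0:
        raise ValueError(f"cobb_major must be > 0, got {cobb_major}")
    if kyphosis <= 0:
        logger.warning(
            "non-positive kyphosis %.2f floored to %.2f deg for deformity index",
            kyphosis,
            kyphosis_floor,
        )
    return cobb_major / max(kyphosis, kyphosis_floor)


def build_feature_matrix(
    records: list[PatientRecord], kyphosis_floor: float = 1.0
) -> FeatureMatrix:
    """Assemble the raw (unstandardized) 6-feature matrix.

    All records must share one etiology.  Records with missing indices
    are excluded with a logged reason; complete rows keep input order.
    """
    if not records:
        raise ValueError("no records supplied")
    etiologies = {r.etiology for r in records}
    if len(etiologies) > 1:
        raise ValueError(f"mixed etiologies in one matrix: {sorted(etiologies)}")

    rows, ids = [], []
    for rec in records:
        if not rec.is_complete:
            logger.info(
                "excluding subject %s: missing %s",
                rec.subject_id,
                ", ".join(rec.missing_fields()),
            )
            continue
        di = compute_deformity_index(rec.cobb_major, rec.kyphosis, kyphosis_floor)
        rows.append([rec.age, rec.cobb_major, rec.kyphosis,
                     rec.levels_cobb, rec.levels_kyphosis, di])
        ids.append(rec.subject_id)
    if not rows:
        raise ValueError("all records had missing indices")
    return FeatureMatrix(
        values=np.asarray(rows, dtype=float),
        subject_ids=tuple(ids),
        etiology=next(iter(etiologies)),
    )


def standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column (sample SD, divisor n-1), storing the scaling.

    Constant columns map to zero with their SD recorded as 1 (warned),
    so the transform remains invertible.  Requires n >= 2.
    """
    if matrix.n < 2:
        raise ValueError("standardization requires at least 2 subjects")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0, ddof=1)
    constant = sd == 0.0
    if constant.any():
        names = [FEATURE_NAMES[i] for i in np.flatnonzero(constant)]
        logger.warning("constant feature column(s) %s mapped to 0", names)
        sd = np.where(constant, 1.0, sd)
    scaling = Scaling(mean=mean, sd=sd)
    return FeatureMatrix(
        values=scaling.transform(matrix.values),
        subject_ids=matrix.subject_ids,
        etiology=matrix.etiology,
        scaling=scaling,
    )


def inverse_standardize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Map a standardized matrix back to original units."""
    if matrix.scaling is None:
        raise ValueError("matrix carries no scaling parameters")
    return replace(
        matrix, values=matrix.scaling.inverse_transform(matrix.values), scaling=None
    )


def record_to_vector(rec: PatientRecord, kyphosis_floor: float = 1.0) -> np.ndarray:
    """Single patient's raw 6-feature vector (used when scoring)."""
    if not rec.is_complete:
        raise ValueError(
            f"subject {rec.subject_id}: missing {', '.join(rec.missing_fields())}"
        )
    di = compute_deformity_index(rec.cobb_major, rec.kyphosis, kyphosis_floor)
    return np.array([rec.age, rec.cobb_major, rec.kyphosis,
                     rec.levels_cobb, rec.levels_kyphosis, di], dtype=float)


def read_patient_csv(path) -> list[PatientRecord]:
    """Read the standard patient table (UTF-8 CSV, exact header names).

    Extra columns are ignored with a log line; rows with unreadable
    etiology are dropped.  Missing numeric fields become NaN and are
    excluded later, when the feature matrix is built.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "etiology": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input CSV missing required columns: {missing_cols}")
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        logger.info("ignoring extra CSV columns: %s", extra)

    records: list[PatientRecord] = []
    for _, row in df.iterrows():
        etiology = row["etiology"]
        if not isinstance(etiology, str) or etiology not in ETIOLOGIES:
            logger.warning(
                "dropping subject %s: unreadable etiology %r",
                row["subject_id"],
                etiology,
            )
            continue
        records.append(
            PatientRecord(
                subject_id=str(row["subject_id"]),
                etiology=etiology,
                age=float(row["age_years"]) if pd.notna(row["age_years"]) else math.nan,
                cobb_major=float(row["cobb_major_deg"]) if pd.notna(row["cobb_major_deg"]) else math.nan,
                kyphosis=float(row["kyphosis_deg"]) if pd.notna(row["kyphosis_deg"]) else math.nan,
                levels_cobb=float(row["levels_cobb"]) if pd.notna(row["levels_cobb"]) else math.nan,
                levels_kyphosis=float(row["levels_kyphosis"]) if pd.notna(row["levels_kyphosis"]) else math.nan,
            )
        )
    return records


def write_patient_csv(records: list[PatientRecord], path) -> None:
    """Write records in the standard patient-table schema."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "etiology": [r.etiology for r in records],
            "age_years": [r.age for r in records],
            "cobb_major_deg": [r.cobb_major for r in records],
            "kyphosis_deg": [r.kyphosis for r in records],
            "levels_cobb": [r.levels_cobb for r in records],
            "levels_kyphosis": [r.levels_kyphosis for r in records],
        }
    )
    # %.17g guarantees float round-tripping through the CSV
    df.to_csv(path, index=False, float_format="%.17g")
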