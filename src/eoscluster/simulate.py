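"""Synthetic EOS cohort generation.

The registry behind the clinical cohorts is private, so every pipeline
stage is exercised on synthetic cohorts with the statistical structure
the analysis assumes: per etiology, a finite Gaussian mixture over the
five measured indices (age, major Cobb angle, kyphosis, levels in the
major curve, levels in kyphosis), truncated to valid clinical ranges,
plus an optional fraction of outliers drawn uniformly over the full
valid ranges.  The deformity index is never sampled — it is computed
from the sampled Cobb and kyphosis exactly as the pipeline computes it
for real data.  Generation is deterministic per seed and returns hidden
ground truth (component labels and outlier flags) for recovery tests.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .features import ETIOLOGIES, PatientRecord

# valid sampling ranges: (low, high) per index
AGE_RANGE = (0.25, 10.0)
ANGLE_RANGE = (10.0, 150.0)
LEVELS_RANGE = (1, 17)

# clinical ranges the component means must respect
MEAN_RANGES = {
    "age": (0.5, 10.0),
    "cobb": (15.0, 140.0),
    "kyphosis": (5.0, 120.0),
    "levels": (3.0, 14.0),
}


class ClusterSpec(BaseModel):
    """One mixture component: weight, 5-vector mean and SD.

    Index order: age (yr), Cobb (deg), kyphosis (deg), levels in major
    curve, levels in kyphosis.  Covariance is diagonal (independent
    indices within a component); pass ``corr`` for a full correlation
    stress test.
    """

    weight: float = Field(gt=0.0, le=1.0)
    mean: list[float]
    sd: list[float]
    corr: list[list[float]] | None = None

    @field_validator("mean", "sd")
    @classmethod
    def _len5(cls, v: list[float]) -> list[float]:
        if len(v) != 5:
            raise ValueError("mean/sd must have 5 entries")
        return v

    @field_validator("sd")
    @classmethod
    def _positive(cls, v: list[float]) -> list[float]:
        if any(s <= 0 for s in v):
            raise ValueError("all SDs must be positive")
        return v

    @model_validator(mode="after")
    def _clinical_ranges(self) -> "ClusterSpec":
        keys = ("age", "cobb", "kyphosis", "levels", "levels")
        for value, key in zip(self.mean, keys):
            lo, hi = MEAN_RANGES[key]
            if not lo <= value <= hi:
                raise ValueError(
                    f"component mean {value} outside clinical range "
                    f"[{lo}, {hi}] for {key}"
                )
        return self


class CohortSpec(BaseModel):
    """A full synthetic cohort: etiology, size, components, outliers."""

    etiology: str
    n_subjects: int = Field(ge=10)
    clusters: list[ClusterSpec]
    outlier_fraction: float = Field(default=0.0, ge=0.0, le=0.2)
    seed: int = 0

    @field_validator("etiology")
    @classmethod
    def _known_etiology(cls, v: str) -> str:
        if v not in ETIOLOGIES:
            raise ValueError(f"etiology must be one of {ETIOLOGIES}")
        return v

    @model_validator(mode="after")
    def _valid_mixture(self) -> "CohortSpec":
        total = sum(c.weight for c in self.clusters)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixing weights sum to {total}, expected 1")
        if self.n_subjects < 10 * len(self.clusters):
            raise ValueError(
                "n_subjects must be at least 10 x number of components"
            )
        return self


def _sample_component(
    rng: np.random.Generator, comp: ClusterSpec, n: int
) -> np.ndarray:
    """Draw n subjects from one component, truncated to valid ranges."""
    mean = np.asarray(comp.mean)
    sd = np.asarray(comp.sd)
    if comp.corr is not None:
        corr = np.asarray(comp.corr)
        cov = corr * np.outer(sd, sd)
        raw = rng.multivariate_normal(mean, cov, size=n)
    else:
        raw = rng.normal(mean, sd, size=(n, 5))
    raw[:, 0] = np.clip(raw[:, 0], *AGE_RANGE)
    raw[:, 1] = np.clip(raw[:, 1], *ANGLE_RANGE)
    raw[:, 2] = np.clip(raw[:, 2], *ANGLE_RANGE)
    raw[:, 3:5] = np.clip(np.rint(raw[:, 3:5]), *LEVELS_RANGE)
    return raw


def _sample_outliers(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform draws over the full valid ranges — points with no cluster."""
    out = np.empty((n, 5))
    out[:, 0] = rng.uniform(*AGE_RANGE, size=n)
    out[:, 1] = rng.uniform(*ANGLE_RANGE, size=n)
    out[:, 2] = rng.uniform(*ANGLE_RANGE, size=n)
    out[:, 3] = rng.integers(LEVELS_RANGE[0], LEVELS_RANGE[1] + 1, size=n)
    out[:, 4] = rng.integers(LEVELS_RANGE[0], LEVELS_RANGE[1] + 1, size=n)
    return out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate one synthetic cohort plus hidden ground truth.

    Exactly ``round(outlier_fraction * n_subjects)`` subjects are
    injected outliers (uniform over the valid ranges); the rest are
    drawn from weight-sampled mixture components.  Returns the patient
    records and a truth table (subject_id, true_component, is_outlier)
    where outliers carry component -1.  Deterministic per spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_out = int(round(spec.outlier_fraction * n))
    n_reg = n - n_out

    weights = np.array([c.weight for c in spec.clusters])
    comp_idx = rng.choice(len(spec.clusters), size=n_reg, p=weights)
    values = np.empty((n, 5))
    components = np.full(n, -1, dtype=int)

    # regular subjects first, then outliers, then a seeded shuffle so
    # outliers are not positionally identifiable
    reg = np.concatenate(
        [
            _sample_component(rng, spec.clusters[j], int((comp_idx == j).sum()))
            for j in range(len(spec.clusters))
        ]
    ) if n_reg else np.empty((0, 5))
    reg_labels = np.concatenate(
        [np.full(int((comp_idx == j).sum()), j) for j in range(len(spec.clusters))]
    ) if n_reg else np.empty(0, dtype=int)

    values[:n_reg] = reg
    components[:n_reg] = reg_labels
    if n_out:
        values[n_reg:] = _sample_outliers(rng, n_out)
    is_outlier = np.zeros(n, dtype=bool)
    is_outlier[n_reg:] = True

    perm = rng.permutation(n)
    values, components, is_outlier = values[perm], components[perm], is_outlier[perm]

    prefix = spec.etiology[:3].upper()
    records = [
        PatientRecord(
            subject_id=f"{prefix}-{i:04d}",
            etiology=spec.etiology,
            age=float(values[i, 0]),
            cobb_major=float(values[i, 1]),
            kyphosis=float(values[i, 2]),
            levels_cobb=float(values[i, 3]),
            levels_kyphosis=float(values[i, 4]),
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "true_component": components,
            "is_outlier": is_outlier,
        }
    )
    return records, truth


def default_specs(
    seed: int = 0,
    n_subjects: int | None = None,
    outlier_fraction: float | None = None,
) -> dict[str, CohortSpec]:
    """Built-in per-etiology cohort specifications.

    Loaded from the versioned ``data/default_cohorts.json`` file: three
    components per etiology in ascending mean Cobb order, with one
    kyphosis-dominant component (mean kyphosis > mean Cobb) in each of
    the neuromuscular and syndromic cohorts and none elsewhere.  Each
    etiology receives a distinct seed derived from ``seed``.
    """
    raw = json.loads(
        resources.files("eoscluster.data")
        .joinpath("default_cohorts.json")
        .read_text(encoding="utf-8")
    )
    n = n_subjects if n_subjects is not None else raw["n_subjects"]
    frac = outlier_fraction if outlier_fraction is not None else raw["outlier_fraction"]
    specs: dict[str, CohortSpec] = {}
    for i, etiology in enumerate(ETIOLOGIES):
        specs[etiology] = CohortSpec(
            etiology=etiology,
            n_subjects=n,
            clusters=[ClusterSpec(**c) for c in raw["etiologies"][etiology]["clusters"]],
            outlier_fraction=frac,
            seed=(seed * 101 + i) % (2**31),
        )
    return specs
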