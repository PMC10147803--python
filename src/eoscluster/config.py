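"""Run configuration for the clustering pipeline.

A single validated config object controls every tunable of a run: the
fuzzy C-means hyperparameters, the candidate cluster counts, the
membership floor used for outlier exclusion, and the significance level
of the post-hoc statistics.  The resolved config is embedded in every
pipeline output so a run can be replayed exactly from (input CSV,
config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator


class FCMConfig(BaseModel):
    """Hyperparameters of the fuzzy C-means fit.

    ``fuzzifier`` is the softness exponent m > 1 (m = 2 is the canonical
    choice, giving inverse-square-distance memberships).  Convergence is
    declared when the largest absolute membership change between
    iterations drops below ``tol``.  ``n_starts`` independent random
    initialisations are fitted and the lowest-objective model kept.
    """

    fuzzifier: float = Field(default=2.0, gt=1.0)
    tol: float = Field(default=1e-6, gt=0.0)
    max_iter: int = Field(default=300, ge=1)
    n_starts: int = Field(default=10, ge=1)


class PipelineConfig(BaseModel):
    """Full pipeline configuration.

    ``k_range`` lists candidate cluster counts (default 2..6);
    ``membership_floor`` is the maximum-membership threshold below which
    a subject is flagged as an outlier; ``alpha`` is the significance
    level for ANOVA/Tukey; ``kyphosis_floor_deg`` is the floor applied
    to kyphosis when forming the deformity index so hypokyphotic
    patients keep a finite ratio.
    """

    seed: int = 0
    k_range: list[int] = Field(default_factory=lambda: [2, 3, 4, 5, 6])
    membership_floor: float = Field(default=0.6, gt=0.0, lt=1.0)
    alpha: float = Field(default=0.01, gt=0.0, lt=1.0)
    refit_after_exclusion: bool = False
    kyphosis_floor_deg: float = Field(default=1.0, gt=0.0)
    fcm: FCMConfig = Field(default_factory=FCMConfig)

    @field_validator("k_range")
    @classmethod
    def _k_range_valid(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("k_range must be non-empty")
        if any(k < 2 for k in v):
            raise ValueError("all candidate k must be >= 2")
        return sorted(set(v))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.model_dump(), indent=2, sort_keys=True), encoding="utf-8"
        )
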