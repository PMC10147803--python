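"""End-to-end cohort analysis and frozen-model patient scoring.

Per etiology: build the six-index feature matrix, z-score it, search
the candidate cluster counts by average membership, flag low-membership
outliers, renumber clusters by ascending mean Cobb angle, tabulate
per-cluster means and SDs, and compare clusters per index with one-way
ANOVA and Tukey HSD.  A completed run yields, per etiology, a frozen
model (centroids + scaling) against which new patients can be scored
without refitting — the per-patient assignment a clinical front end
would perform.  Every output embeds the resolved configuration, and a
run is byte-identical given the same input, config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from .config import PipelineConfig
from .fcm import ClusterModel, fcm_fit, update_memberships
from .selection import SelectionResult, canonical_ordering, flag_outliers, select_k
from .stats import AnovaResult, TukeyResult, one_way_anova, tukey_hsd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EtiologyResult:
    """Everything the analysis produces for one etiology."""

    etiology: str
    n_eligible: int
    n_excluded_missing: int
    n_outliers: int
    n_included: int
    selection: SelectionResult
    model: ClusterModel  # canonical cluster order
    assignments: pd.DataFrame  # subject_id, cluster, max_membership, outlier
    summary_table: pd.DataFrame  # per-cluster mean/SD of all six indices
    anova: tuple[AnovaResult, ...]
    tukey: tuple[TukeyResult, ...]
    scatter_export: pd.DataFrame  # cobb_major_deg, kyphosis_deg, cluster

    def __post_init__(self) -> None:
        if self.n_included != self.n_eligible - self.n_excluded_missing - self.n_outliers:
            raise ValueError("subject accounting does not balance")

    def to_dict(self) -> dict:
        return {
            "etiology": self.etiology,
            "counts": {
                "n_eligible": self.n_eligible,
                "n_excluded_missing": self.n_excluded_missing,
                "n_outliers": self.n_outliers,
                "n_included": self.n_included,
            },
            "selection": self.selection.to_dict(),
            "model": self.model.to_dict(),
            "assignments": self.assignments.to_dict(orient="records"),
            "summary_table": self.summary_table.to_dict(orient="records"),
            "anova": [a.to_dict() for a in self.anova],
            "tukey": [t.to_dict() for t in self.tukey],
        }


@dataclass(frozen=True)
class ActReport:
    """Results for all requested etiologies plus skip reasons and config."""

    results: dict[str, EtiologyResult]
    skipped: dict[str, str]
    config: PipelineConfig

    def to_dict(self) -> dict:
        return {
            "config": self.config.model_dump(),
            "results": {e: r.to_dict() for e, r in self.results.items()},
            "skipped": dict(self.skipped),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _summaries(
    raw: np.ndarray, assignments: np.ndarray, flags: np.ndarray, k: int
) -> pd.DataFrame:
    """Per-cluster mean +/- SD of the six indices over retained subjects."""
    rows = []
    for label in range(1, k + 1):
        members = (assignments == label) & ~flags
        sub = raw[members]
        row: dict = {"cluster": label, "n": int(members.sum())}
        for col, name in enumerate(ft.FEATURE_NAMES):
            row[f"{name}_mean"] = float(sub[:, col].mean()) if len(sub) else np.nan
            row[f"{name}_sd"] = (
                float(sub[:, col].std(ddof=1)) if len(sub) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_etiology(
    records: list[ft.PatientRecord], config: PipelineConfig
) -> EtiologyResult:
    """Run the full clustering analysis for one etiology's records."""
    etiology = records[0].etiology
    n_eligible = len(records)

    raw_fm = ft.build_feature_matrix(records, config.kyphosis_floor_deg)
    n_excluded_missing = n_eligible - raw_fm.n
    std_fm = ft.standardize(raw_fm)

    sel = select_k(
        std_fm.values,
        k_range=config.k_range,
        fcm_config=config.fcm,
        seed=config.seed,
        membership_floor=config.membership_floor,
        scaling=std_fm.scaling,
    )
    model = sel.best_model
    flags = sel.outlier_flags

    if config.refit_after_exclusion and flags.any():
        logger.info(
            "%s: refitting at k=%d after excluding %d outliers",
            etiology, sel.best_k, int(flags.sum()),
        )
        kept = ~flags
        refit = fcm_fit(
            std_fm.values[kept], sel.best_k,
            m=config.fcm.fuzzifier, tol=config.fcm.tol,
            max_iter=config.fcm.max_iter, n_starts=config.fcm.n_starts,
            seed=config.seed, scaling=std_fm.scaling,
        )
        # re-evaluate every subject (incl. outliers) against refit centroids
        U_all = update_memberships(std_fm.values, refit.centroids_std,
                                   config.fcm.fuzzifier)
        model = ClusterModel(
            k=refit.k, fuzzifier_m=refit.fuzzifier_m,
            centroids_std=refit.centroids_std, memberships=U_all,
            objective_trace=refit.objective_trace, converged=refit.converged,
            seed=refit.seed, n_iter=refit.n_iter, scaling=std_fm.scaling,
        )
        flags = flag_outliers(U_all, config.membership_floor)

    cobb_raw = raw_fm.values[:, 1]
    model, assignments, _ = canonical_ordering(model, cobb_raw, flags)
    n_outliers = int(flags.sum())
    n_included = raw_fm.n - n_outliers

    assign_df = pd.DataFrame(
        {
            "subject_id": list(raw_fm.subject_ids),
            "cluster": np.where(flags, 0, assignments),
            "max_membership": model.memberships.max(axis=1),
            "outlier": flags,
        }
    )
    summary = _summaries(raw_fm.values, assignments, flags, model.k)

    anovas, tukeys = [], []
    kept_assign = assignments[~flags]
    kept_raw = raw_fm.values[~flags]
    for col, name in enumerate(ft.FEATURE_NAMES):
        groups = [kept_raw[kept_assign == label, col] for label in range(1, model.k + 1)]
        anovas.append(one_way_anova(groups, index_name=name))
        tukeys.append(tukey_hsd(groups, alpha=config.alpha, index_name=name))

    scatter = pd.DataFrame(
        {
            "cobb_major_deg": raw_fm.values[:, 1],
            "kyphosis_deg": raw_fm.values[:, 2],
            "cluster": np.where(flags, 0, assignments),  # 0 marks outliers
        }
    )

    return EtiologyResult(
        etiology=etiology,
        n_eligible=n_eligible,
        n_excluded_missing=n_excluded_missing,
        n_outliers=n_outliers,
        n_included=n_included,
        selection=sel,
        model=model,
        assignments=assign_df,
        summary_table=summary,
        anova=tuple(anovas),
        tukey=tuple(tukeys),
        scatter_export=scatter,
    )


def run_act(
    records: list[ft.PatientRecord], config: PipelineConfig | None = None
) -> ActReport:
    """Cluster every etiology present in the input.

    Each of the four etiologies gets its own analysis; an etiology with
    too few subjects (fewer than max(k_range) + 1) or no records at all
    is reported as skipped with the reason.
    """
    config = config or PipelineConfig()
    by_etiology: dict[str, list[ft.PatientRecord]] = {e: [] for e in ft.ETIOLOGIES}
    for rec in records:
        by_etiology[rec.etiology].append(rec)

    min_n = max(config.k_range) + 1
    results: dict[str, EtiologyResult] = {}
    skipped: dict[str, str] = {}
    for etiology, recs in by_etiology.items():
        if not recs:
            skipped[etiology] = "no records"
            continue
        if len(recs) < min_n:
            skipped[etiology] = (
                f"only {len(recs)} subjects; need at least {min_n} "
                f"for k up to {max(config.k_range)}"
            )
            logger.warning("skipping %s: %s", etiology, skipped[etiology])
            continue
        results[etiology] = analyze_etiology(recs, config)
    return ActReport(results=results, skipped=skipped, config=config)


def score_new_patient(
    record: ft.PatientRecord,
    model: ClusterModel,
    membership_floor: float = 0.6,
    kyphosis_floor: float = 1.0,
) -> tuple[int, np.ndarray, bool]:
    """Assign one new patient against a frozen fitted model.

    The patient's six-index vector is standardized with the model's
    stored scaling and evaluated against the frozen centroids; no
    refitting occurs.  Returns (canonical cluster label, membership
    vector, outlier flag at the floor).  Stateless: scoring a batch
    record-by-record gives identical results.
    """
    if model.scaling is None:
        raise ValueError("model carries no scaling; fit through the pipeline")
    x_raw = ft.record_to_vector(record, kyphosis_floor)
    x_std = model.scaling.transform(x_raw)
    u = update_memberships(x_std[None, :], model.centroids_std, model.fuzzifier_m)[0]
    label = int(u.argmax()) + 1
    return label, u, bool(u.max() < membership_floor)


def write_outputs(report: ActReport, out_dir: str | Path) -> None:
    """Write the per-etiology JSON, summary CSVs and scatter exports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    for etiology, res in report.results.items():
        res.model.save_json(out / f"{etiology}_model.json")
        res.summary_table.to_csv(out / f"{etiology}_summary.csv", index=False)
        res.scatter_export.to_csv(out / f"{etiology}_scatter.csv", index=False)
        res.assignments.to_csv(out / f"{etiology}_assignments.csv", index=False)
    tidy_rows = []
    for etiology, res in report.results.items():
        for a in res.anova:
            tidy_rows.append(
                {"etiology": etiology, "index": a.index_name, "comparison": "anova",
                 "statistic": a.f_stat, "p": a.p_value,
                 "significant": a.p_value < report.config.alpha}
            )
        for t in res.tukey:
            for ca, cb, diff, p, sig in t.pairs:
                tidy_rows.append(
                    {"etiology": etiology, "index": t.index_name,
                     "comparison": f"tukey_{ca}v{cb}", "statistic": diff,
                     "p": p, "significant": sig}
                )
    pd.DataFrame(tidy_rows).to_csv(out / "statistics.csv", index=False)
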