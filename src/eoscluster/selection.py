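"""Cluster-count selection, membership-floor outliers, canonical order.

The number of clusters is chosen by refitting over a candidate range
and keeping the k whose model attains the highest average membership —
the mean over subjects of each subject's maximum membership, the same
per-subject confidence scalar that the outlier rule thresholds.
Subjects whose maximum membership falls strictly below the floor
(default 0.6) are flagged as outliers: they belong to no cluster with
sufficient certainty and are excluded from summary statistics.  Cluster
labels are finally renumbered 1..k in ascending order of the mean major
Cobb angle of each cluster's retained members, so "cluster 1" is always
the mildest coronal deformity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .config import FCMConfig
from .fcm import ClusterModel, fcm_fit
from .features import Scaling

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the cluster-count search for one cohort."""

    candidate_ks: tuple[int, ...]
    avg_membership_by_k: dict[int, float]
    best_k: int
    models: dict[int, ClusterModel]
    outlier_flags: np.ndarray
    membership_floor: float

    @property
    def best_model(self) -> ClusterModel:
        return self.models[self.best_k]

    def to_dict(self) -> dict:
        return {
            "candidate_ks": list(self.candidate_ks),
            "avg_membership_by_k": {
                str(k): float(v) for k, v in self.avg_membership_by_k.items()
            },
            "best_k": self.best_k,
            "membership_floor": self.membership_floor,
            "n_outliers": int(self.outlier_flags.sum()),
        }


def average_membership(U: np.ndarray) -> float:
    """Mean over subjects of their maximum membership value."""
    U = np.asarray(U, dtype=float)
    if U.size == 0:
        raise ValueError("empty membership matrix")
    return float(U.max(axis=1).mean())


def flag_outliers(U: np.ndarray, floor: float = 0.6) -> np.ndarray:
    """Flag subjects whose maximum membership is strictly below the floor.

    A subject with membership exactly at the floor is retained; raising
    the floor can only flag more subjects, never fewer.
    """
    if not 0.0 < floor < 1.0:
        raise ValueError(f"floor must be in (0, 1), got {floor}")
    return np.asarray(U).max(axis=1) < floor


def select_k(
    X: np.ndarray,
    k_range: list[int] | tuple[int, ...] = (2, 3, 4, 5, 6),
    fcm_config: FCMConfig | None = None,
    seed: int = 0,
    membership_floor: float = 0.6,
    scaling: Scaling | None = None,
) -> SelectionResult:
    """Fit FCM at every candidate k and keep the highest-average-membership model.

    All candidates use identical configuration and seed.  Ties break to
    the smaller k (parsimony).  Candidates with k > n are skipped with a
    warning.  Outliers are flagged on the winning model.
    """
    cfg = fcm_config or FCMConfig()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]

    models: dict[int, ClusterModel] = {}
    avg: dict[int, float] = {}
    tried: list[int] = []
    for k in sorted(set(int(k) for k in k_range)):
        if k > n:
            logger.warning("skipping k=%d: only %d subjects", k, n)
            continue
        model = fcm_fit(
            X, k,
            m=cfg.fuzzifier, tol=cfg.tol, max_iter=cfg.max_iter,
            n_starts=cfg.n_starts, seed=seed, scaling=scaling,
        )
        models[k] = model
        avg[k] = average_membership(model.memberships)
        tried.append(k)
    if not models:
        raise ValueError("no feasible candidate k for this cohort size")

    # argmax with ties broken to smaller k: iterate ascending, strict >
    best_k = tried[0]
    for k in tried[1:]:
        if avg[k] > avg[best_k]:
            best_k = k

    uniform_baseline = 1.0 / best_k + 0.1
    if avg[best_k] < uniform_baseline:
        logger.warning(
            "weak cluster structure: best average membership %.3f at k=%d "
            "is close to the uniform value 1/k", avg[best_k], best_k
        )

    flags = flag_outliers(models[best_k].memberships, membership_floor)
    return SelectionResult(
        candidate_ks=tuple(tried),
        avg_membership_by_k=avg,
        best_k=best_k,
        models=models,
        outlier_flags=flags,
        membership_floor=membership_floor,
    )


def canonical_ordering(
    model: ClusterModel,
    cobb_raw: np.ndarray,
    outlier_flags: np.ndarray | None = None,
) -> tuple[ClusterModel, np.ndarray, dict[int, int]]:
    """Renumber clusters 1..k by ascending mean major Cobb angle.

    ``cobb_raw`` holds each subject's raw Cobb angle (degrees), aligned
    with membership rows.  Cluster means are taken over non-outlier
    members (argmax assignment); a cluster with no retained members
    falls back to its centroid's raw Cobb value (logged).  Exact ties
    keep the lower original index first.  Returns the relabeled model,
    1-based canonical assignments, and the old-index -> new-label map.
    """
    U = model.memberships
    n, k = U.shape
    cobb_raw = np.asarray(cobb_raw, dtype=float)
    if cobb_raw.shape[0] != n:
        raise ValueError("cobb_raw must align with membership rows")
    flags = (np.zeros(n, dtype=bool) if outlier_flags is None
             else np.asarray(outlier_flags, dtype=bool))

    hard = U.argmax(axis=1)
    centroid_cobb = model.centroids_raw[:, 1]
    means = np.empty(k)
    for j in range(k):
        members = (hard == j) & ~flags
        if members.any():
            means[j] = cobb_raw[members].mean()
        else:
            logger.warning(
                "cluster %d has no retained members; ordering by centroid Cobb", j
            )
            means[j] = centroid_cobb[j]

    if np.unique(means).size < k:
        logger.info("exact tie in mean Cobb; lower original cluster index first")
    order = np.lexsort((np.arange(k), means))  # stable: ties keep lower index
    label_map = {int(old): int(new + 1) for new, old in enumerate(order)}

    relabeled = replace(
        model,
        centroids_std=model.centroids_std[order],
        memberships=U[:, order],
    )
    assignments = np.array([label_map[int(j)] for j in hard], dtype=int)
    return relabeled, assignments, label_map
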