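"""Fuzzy C-means clustering (Bezdek formulation).

Soft clustering by alternating optimisation of the fuzzified
within-cluster sum of squares

    J(U, V) = sum_i sum_j  u_ij^m  ||x_i - v_j||^2,

where U is the row-stochastic membership matrix, V the centroids and
m > 1 the fuzzifier.  Memberships are inverse-distance ratios

    u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1)),

and centroids are membership-weighted means.  Each alternating step can
only decrease J, so the objective trace is non-increasing; this is
checked on every fit.  Fits are multi-start (random Dirichlet
membership initialisations) and fully seeded, so a model is reproducible
bit-for-bit from its configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import Scaling

logger = logging.getLogger(__name__)

# squared distances at or below this are treated as exact coincidence
# with a centroid (singularity rule)
_ZERO_DIST_SQ = 1e-24


@dataclass(frozen=True)
class ClusterModel:
    """A fitted fuzzy C-means model for one etiology.

    Centroids are stored both in standardized space (where the fit ran)
    and in original clinical units via the stored scaling.  The
    objective trace holds J after every iteration of the winning start.
    """

    k: int
    fuzzifier_m: float
    centroids_std: np.ndarray
    memberships: np.ndarray
    objective_trace: tuple[float, ...]
    converged: bool
    seed: int
    n_iter: int
    scaling: Scaling | None = field(default=None)

    @property
    def centroids_raw(self) -> np.ndarray:
        """Centroids mapped back to original clinical units."""
        if self.scaling is None:
            return self.centroids_std.copy()
        return self.scaling.inverse_transform(self.centroids_std)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "fuzzifier_m": self.fuzzifier_m,
            "centroids_std": [[float(x) for x in row] for row in self.centroids_std],
            "seed": self.seed,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "scaling": self.scaling.to_dict() if self.scaling else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        centroids = np.asarray(d["centroids_std"], dtype=float)
        return cls(
            k=int(d["k"]),
            fuzzifier_m=float(d["fuzzifier_m"]),
            centroids_std=centroids,
            memberships=np.zeros((0, centroids.shape[0])),
            objective_trace=(),
            converged=bool(d.get("converged", True)),
            seed=int(d.get("seed", 0)),
            n_iter=int(d.get("n_iter", 0)),
            scaling=Scaling.from_dict(d["scaling"]) if d.get("scaling") else None,
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "ClusterModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _sq_distances(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - V[None, :, :]
    return np.einsum("nkd,nkd->nk", diff, diff)


def update_memberships(X: np.ndarray, V: np.ndarray, m: float) -> np.ndarray:
    """Membership update: row-stochastic inverse-distance ratios.

    A point coincident with a centroid gets full membership there; a
    point coincident with several centroids splits membership equally
    among them.
    """
    if m <= 1.0:
        raise ValueError(f"fuzzifier must be > 1, got {m}")
    d2 = _sq_distances(X, V)
    zero = d2 <= _ZERO_DIST_SQ
    any_zero = zero.any(axis=1)

    # normalise by the row-minimum distance before powering: identical
    # ratios, but stable for small m where the exponent is large
    U = np.empty_like(d2)
    ok = ~any_zero
    d2_ok = d2[ok]
    ratio = d2_ok / d2_ok.min(axis=1, keepdims=True)
    inv = ratio ** (-1.0 / (m - 1.0))
    U[ok] = inv / inv.sum(axis=1, keepdims=True)
    if any_zero.any():
        U[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        n_ties = int((zero[any_zero].sum(axis=1) > 1).sum())
        if n_ties:
            logger.info("%d point(s) coincident with multiple centroids; "
                        "membership split equally", n_ties)
    return U


def update_centroids(
    X: np.ndarray, U: np.ndarray, m: float
) -> np.ndarray:
    """Centroid update: membership-weighted means.

    A cluster whose total weight underflows to zero is rescued by
    re-seeding its centroid at the point with the worst maximum
    membership (logged).
    """
    W = U**m
    total = W.sum(axis=0)
    empty = total <= 0.0
    if empty.any():
        worst = int(np.argmin(U.max(axis=1)))
        logger.warning(
            "empty cluster(s) %s re-seeded at subject row %d",
            np.flatnonzero(empty).tolist(),
            worst,
        )
        V = np.empty((U.shape[1], X.shape[1]))
        nonempty = ~empty
        V[nonempty] = (W[:, nonempty].T @ X) / total[nonempty, None]
        V[empty] = X[worst]
        return V
    return (W.T @ X) / total[:, None]


def objective(X: np.ndarray, V: np.ndarray, U: np.ndarray, m: float) -> float:
    """Fuzzified within-cluster sum of squares J(U, V)."""
    return float((U**m * _sq_distances(X, V)).sum())


def fcm_fit(
    X: np.ndarray,
    k: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_starts: int = 10,
    seed: int = 0,
    scaling: Scaling | None = None,
) -> ClusterModel:
    """Fit fuzzy C-means with multi-start alternating optimisation.

    Each start draws a random row-stochastic membership matrix from a
    symmetric Dirichlet(1) and alternates centroid/membership updates
    until the maximum absolute membership change falls below ``tol`` or
    ``max_iter`` is reached.  The start with the lowest final objective
    wins.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    n = X.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} subjects, got n={n}")
    if m <= 1.0:
        raise ValueError(f"fuzzifier must be > 1, got {m}")
    if tol <= 0:
        raise ValueError("tol must be > 0")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, list[float], bool, int] | None = None
    for _ in range(n_starts):
        U = rng.dirichlet(np.ones(k), size=n)
        trace: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            V = update_centroids(X, U, m)
            U_new = update_memberships(X, V, m)
            trace.append(objective(X, V, U_new, m))
            delta = np.abs(U_new - U).max()
            U = U_new
            if delta < tol:
                converged = True
                break
        final = trace[-1]
        if best is None or final < best[0]:
            best = (final, V, U, trace, converged, n_iter)

    assert best is not None
    _, V, U, trace, converged, n_iter = best
    if not converged:
        logger.warning("FCM did not converge within %d iterations (k=%d)",
                       max_iter, k)
    return ClusterModel(
        k=k,
        fuzzifier_m=m,
        centroids_std=V,
        memberships=U,
        objective_trace=tuple(trace),
        converged=converged,
        seed=seed,
        n_iter=n_iter,
        scaling=scaling,
    )
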