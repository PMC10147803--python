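"""Between-cluster comparison of clinical indices.

One-way ANOVA per index (classic between/within sum-of-squares
decomposition, F = MS_between / MS_within) followed by Tukey's HSD
post-hoc test over all cluster pairs, using the studentized range with
the Tukey–Kramer harmonic correction for unequal group sizes.  The
default significance level is 0.01.  Outlier-flagged subjects are
excluded upstream, so groups contain retained subjects only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaResult:
    index_name: str
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    group_ns: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "group_means": list(self.group_means),
            "group_sds": list(self.group_sds),
            "group_ns": list(self.group_ns),
        }


@dataclass(frozen=True)
class TukeyResult:
    """All k(k-1)/2 unordered pairwise comparisons, each exactly once."""

    index_name: str
    alpha: float
    pairs: tuple[tuple[int, int, float, float, bool], ...]
    # (cluster_a, cluster_b, mean_diff, adjusted_p, significant)

    def to_dict(self) -> dict:
        return {
            "index": self.index_name,
            "alpha": self.alpha,
            "pairs": [
                {"cluster_a": a, "cluster_b": b, "mean_diff": d,
                 "adjusted_p": p, "significant": s}
                for a, b, d, p, s in self.pairs
            ],
        }


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"cluster {i + 1} has fewer than 2 subjects (n={g.size})")
    return arrs


def one_way_anova(groups: list[np.ndarray], index_name: str = "") -> AnovaResult:
    """Classic one-way fixed-effects ANOVA.

    SS_between = sum n_j (mean_j - grand)^2 on k-1 df, SS_within =
    pooled squared deviations on N-k df, F their mean-square ratio with
    p from the upper F tail.  Zero within-variance with non-zero
    between-variance reports p = 0 with a warning.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    ns = np.array([g.size for g in arrs])
    N = int(ns.sum())
    means = np.array([g.mean() for g in arrs])
    grand = np.concatenate(arrs).mean()

    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrs))
    df_b, df_w = k - 1, N - k

    if ss_within == 0.0:
        if ss_between > 0.0:
            logger.warning(
                "%s: zero within-group variance with non-zero between; p = 0",
                index_name or "anova",
            )
            f_stat, p = np.inf, 0.0
        else:
            f_stat, p = 0.0, 1.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))

    return AnovaResult(
        index_name=index_name,
        f_stat=float(f_stat),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        group_means=tuple(float(m) for m in means),
        group_sds=tuple(float(g.std(ddof=1)) for g in arrs),
        group_ns=tuple(int(n) for n in ns),
    )


def tukey_hsd(
    groups: list[np.ndarray], alpha: float = 0.01, index_name: str = ""
) -> TukeyResult:
    """Tukey's HSD over all unordered cluster pairs.

    Adjusted p-values come from the studentized-range distribution;
    unequal group sizes use the Tukey–Kramer harmonic form.  Cluster
    labels in the result are 1-based, matching canonical cluster
    numbering.
    """
    arrs = _check_groups(groups)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    res = sps.tukey_hsd(*arrs)
    pairs = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            diff = float(arrs[i].mean() - arrs[j].mean())
            p = float(res.pvalue[i, j])
            pairs.append((i + 1, j + 1, diff, p, p < alpha))
    return TukeyResult(index_name=index_name, alpha=alpha, pairs=tuple(pairs))
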