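"""Nonparametric group statistics for per-electrode metrics.

Electrode-level spike/burst/discharge metrics are skewed and heteroscedastic,
so two-group comparisons use the Mann-Whitney U test, three or more groups use
Kruskal-Wallis followed by Dunn's multiple-comparison test
(Bonferroni-adjusted), treatment effects are expressed as percent of baseline
(unchanged activity = 100%), and outliers are removed with a ROUT-style
FDR-controlled procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    group_labels: list[str]
    group_n: list[int]
    #: for Dunn: [((label_i, label_j), z, adjusted_p), ...]
    pairwise: list[tuple[tuple[str, str], float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def significance_stars(p: float) -> str:
    """Prism-style stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def percent_change(values: np.ndarray, baseline_values: np.ndarray) -> np.ndarray:
    """Per-electrode percentage of baseline: 100 * value / baseline.

    Values and baselines are paired elementwise (one pair per electrode).
    Electrodes with a zero baseline are excluded with a warning — a percent
    change from nothing is undefined.
    """
    v = np.asarray(values, dtype=float)
    b = np.asarray(baseline_values, dtype=float)
    if v.shape != b.shape:
        raise ValueError("values and baselines must be paired elementwise")
    keep = b != 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} electrode(s) with zero baseline",
            stacklevel=2,
        )
    return 100.0 * v[keep] / b[keep]


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def mann_whitney(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> GroupComparison:
    """Mann-Whitney U test.

    Uses the exact null distribution when the smaller group has <= 8
    observations and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        # all observations identical: no evidence either way
        return GroupComparison(
            "mann_whitney", a.size * b.size / 2.0, 1.0, ["a", "b"], [a.size, b.size]
        )
    exact = min(a.size, b.size) <= 8 and not _has_ties(a, b)
    res = sstats.mannwhitneyu(
        a, b, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return GroupComparison(
        "mann_whitney",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        ["a", "b"],
        [a.size, b.size],
    )


def kruskal_dunn(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> GroupComparison:
    """Kruskal-Wallis H test (tie-corrected, chi-square p) with Dunn's
    post-hoc z tests on pooled ranks, Bonferroni-adjusted.

    Fewer than 3 groups is a usage error: use :func:`mann_whitney` instead.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups; use mann_whitney for 2")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    labels = labels or [f"g{i}" for i in range(len(groups))]

    pooled = np.concatenate(groups)
    n_total = pooled.size
    if np.unique(pooled).size == 1:
        h_stat, p = 0.0, 1.0
    else:
        h_stat, p = sstats.kruskal(*groups)

    # Dunn: z_ij = (rbar_i - rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    # with tie term T = sum(t^3 - t) / (12 (N - 1))
    ranks = sstats.rankdata(pooled)
    bounds = np.cumsum([0] + [g.size for g in groups])
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    m = len(groups) * (len(groups) - 1) // 2
    pairwise = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_unadj = 2.0 * sstats.norm.sf(abs(z))
        pairwise.append(((labels[i], labels[j]), float(z), float(min(1.0, p_unadj * m))))

    return GroupComparison(
        "kruskal_dunn",
        float(h_stat),
        float(p),
        labels,
        [g.size for g in groups],
        pairwise=pairwise,
    )


def rout_outliers(
    values: np.ndarray, q: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """ROUT-style outlier flagging for a one-sample location model.

    The full procedure couples robust nonlinear regression with FDR-controlled
    outlier calls; applied to scalar per-electrode metrics the model collapses
    to a constant, so: fit the median, scale residuals by the robust standard
    deviation (68.27th percentile of |residuals|, small-sample corrected),
    convert to two-sided t-tail p-values (df = n-1) and flag with a
    Benjamini-Hochberg step at rate ``q`` (default 1%, the conventional Q).

    Returns ``(kept_mask, flagged_values)``.
    """
    v = np.asarray(values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if v.size < 3:
        warnings.warn("fewer than 3 values: outlier detection skipped", stacklevel=2)
        return np.ones(v.size, dtype=bool), v[:0]
    resid = v - np.median(v)
    abs_resid = np.abs(resid)
    rsdr = np.percentile(abs_resid, 68.27) * np.sqrt(v.size / (v.size - 1))
    if rsdr == 0:
        return np.ones(v.size, dtype=bool), v[:0]
    t = abs_resid / rsdr
    pvals = 2.0 * sstats.t.sf(t, df=v.size - 1)
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return ~reject, v[reject]
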