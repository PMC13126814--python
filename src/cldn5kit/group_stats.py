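"""Group-level statistics: deltas, bootstrap CIs, exact rank tests,
log-space mean ratios, normality gating and FDR.

The seam design gives only n = 4 replicate systems per isoform, so the
machinery here is built for very small samples: the Mann-Whitney U test
uses the exact conditional permutation distribution (with mid-rank ties)
whenever the combined sample is small, confidence intervals come from a
seeded percentile bootstrap, and ratios of group means of quantities
carried in log10 are evaluated by log-sum-exp so that values spanning
tens of orders of magnitude never overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "GroupComparison",
    "LogRatio",
    "delta_means",
    "bootstrap_ci",
    "mann_whitney_u",
    "ratio_of_group_means",
    "shapiro_gate",
    "bh_fdr",
    "compare_groups",
    "EXACT_MWU_MAX_N",
]

#: Largest combined sample size for which the Mann-Whitney p-value is
#: computed by full enumeration of the conditional permutation distribution.
EXACT_MWU_MAX_N = 12


@dataclass(frozen=True)
class GroupComparison:
    """Difference of group means with bootstrap CI and rank-test p."""

    metric_name: str
    delta: float          # mean(group_a) - mean(group_b)
    ci_low: float
    ci_high: float
    p_value: float
    n_resamples: int
    test_name: str

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class LogRatio:
    """log10 of a ratio of arithmetic group means; flagged when degenerate."""

    value: float
    degenerate: bool = False


def delta_means(metric: str, group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """mean(group_a) − mean(group_b); antisymmetric in its groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"{metric}: both groups must be non-empty")
    return float(a.mean() - b.mean())


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of a statistic of one sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("sample must contain at least one value")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    stat = np.apply_along_axis(statistic, 1, x[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stat, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test.

    For combined samples of at most ``EXACT_MWU_MAX_N`` observations the
    p-value is exact: mid-ranks are assigned to the pooled sample and all
    C(n_a+n_b, n_a) assignments of ranks to group A are enumerated,
    giving the conditional distribution of U given the observed ties.
    The two-tailed p is the probability mass at or beyond the observed U
    and its reflection n_a·n_b − U.  Larger samples use the
    tie-corrected normal approximation with continuity correction.

    Returns (U of group A, two-tailed p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    u_obs = _u_statistic(ranks[:n_a], n_a)

    if n_a + n_b <= EXACT_MWU_MAX_N:
        u_lo = min(u_obs, n_a * n_b - u_obs)
        u_hi = max(u_obs, n_a * n_b - u_obs)
        n_total = 0
        n_extreme = 0
        eps = 1e-9
        for combo in combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(combo)], n_a)
            n_total += 1
            if u <= u_lo + eps or u >= u_hi - eps:
                n_extreme += 1
        p = min(1.0, n_extreme / n_total)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return u_obs, p


def ratio_of_group_means(
    log10_a: Sequence[float], log10_b: Sequence[float]
) -> LogRatio:
    """log10 of the ratio of arithmetic group means for values given in log10.

    Computed by log-sum-exp so that exponents spanning many tens of
    decades never overflow.  If either group is −inf throughout (all
    underlying values zero) the result is flagged degenerate.
    """
    a = np.asarray(log10_a, dtype=float)
    b = np.asarray(log10_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(np.isnan(a)) or np.any(np.isnan(b)) or np.any(a == np.inf) or np.any(b == np.inf):
        raise ValueError("log10 values must be finite or -inf")
    ln10 = math.log(10.0)
    if np.all(np.isneginf(a)) or np.all(np.isneginf(b)):
        return LogRatio(value=float("nan"), degenerate=True)
    log_mean_a = (logsumexp(a * ln10) - math.log(a.size)) / ln10
    log_mean_b = (logsumexp(b * ln10) - math.log(b.size)) / ln10
    return LogRatio(value=float(log_mean_a - log_mean_b), degenerate=False)


def shapiro_gate(values: Sequence[float], alpha: float = 0.05) -> tuple[str, str | None]:
    """Decide parametric vs nonparametric analysis by Shapiro-Wilk.

    Returns (decision, flag); decision is ``"parametric"`` or
    ``"nonparametric"``.  Undersized (n < 3) or zero-variance samples
    cannot be tested and default to nonparametric with a flag.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        return "nonparametric", "too few"
    if np.ptp(x) == 0:
        return "nonparametric", "degenerate"
    p = float(sps.shapiro(x).pvalue)
    return ("parametric" if p >= alpha else "nonparametric"), None


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return np.asarray(q, dtype=float)


def compare_groups(
    metric_name: str,
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_resamples: int = 10_000,
    level: float = 0.95,
    seed: int | None = 0,
) -> GroupComparison:
    """Full two-group comparison of one metric: Δ of means, percentile
    bootstrap CI of the difference (both groups resampled jointly), and
    the exact/asymptotic Mann-Whitney p."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    delta = delta_means(metric_name, a, b)
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_resamples, a.size))
    ib = rng.integers(0, b.size, size=(n_resamples, b.size))
    diffs = a[ia].mean(axis=1) - b[ib].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    _, p = mann_whitney_u(a, b)
    test = (
        "mann-whitney-exact"
        if a.size + b.size <= EXACT_MWU_MAX_N
        else "mann-whitney-asymptotic"
    )
    return GroupComparison(
        metric_name=metric_name,
        delta=delta,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        n_resamples=n_resamples,
        test_name=test,
    )
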