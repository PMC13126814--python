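"""Isoform-outcome correlation analysis for a stroke cohort.

Each animal carries densitometry ratios for three claudin-5
immunoreactive species — isoform 1 (~35 kDa), isoform 2 (~25 kDa) and a
~10 kDa fragment, each normalised to β-actin on the same lane — and
outcome measures: infarct volume, vasogenic edema volume, hemorrhage
volume (mm³) and a 28-point neuroscore (28 = normal function, lower is
worse).

The analysis fits one simple linear regression per (isoform, outcome)
pair on pairwise-complete data, reports raw slope-t p-values together
with Benjamini-Hochberg q-values across the whole family as a
multiple-testing sensitivity analysis, supports a severe-hemorrhage
exclusion (volume strictly greater than a threshold, 5 mm³ by default),
and offers a simplified ROUT-style outlier screen: a robust line fit,
residuals scaled by a robust scale estimate, and an FDR test on the
residual t-values.  Flags are advisory; no data point is ever silently
removed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .group_stats import bh_fdr

__all__ = [
    "CohortRecord",
    "CorrelationResult",
    "PREDICTOR_COLUMNS",
    "OUTCOME_COLUMNS",
    "read_cohort",
    "write_cohort",
    "fit_linreg",
    "correlate_outcomes",
    "sensitivity_exclude_severe",
    "rout_flag_outliers",
]

PREDICTOR_COLUMNS = ("iso1_density", "iso2_density", "fragment_density")
OUTCOME_COLUMNS = ("infarct_volume", "edema_volume", "hemorrhage_volume", "neuroscore")
COHORT_COLUMNS = ("animal_id",) + PREDICTOR_COLUMNS + OUTCOME_COLUMNS

# zero-residual guard: SSE below this fraction of SST counts as a perfect fit
_PERFECT_FIT_RTOL = 1e-12


@dataclass(frozen=True)
class CohortRecord:
    """One animal's densitometry and outcome measures (NaN = missing)."""

    animal_id: str
    iso1_density: float
    iso2_density: float
    fragment_density: float
    infarct_volume: float
    edema_volume: float
    hemorrhage_volume: float
    neuroscore: float

    def __post_init__(self) -> None:
        for f in PREDICTOR_COLUMNS:
            v = getattr(self, f)
            if not np.isnan(v) and v < 0:
                raise ValueError(f"{self.animal_id}: {f} must be >= 0")
        ns = self.neuroscore
        if not np.isnan(ns) and not (0 <= ns <= 28):
            raise ValueError(f"{self.animal_id}: neuroscore must lie in [0, 28]")


@dataclass(frozen=True)
class CorrelationResult:
    predictor: str
    outcome: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    q_value: float   # NaN until the family-wise FDR pass fills it in
    n_used: int
    degenerate: bool = False


def read_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Load a cohort CSV (one row per animal, CohortRecord column names)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing column(s) {missing}")
    # run the record-level validation on every row
    for rec in df[list(COHORT_COLUMNS)].itertuples(index=False):
        CohortRecord(str(rec.animal_id), *[float(v) for v in rec[1:]])
    return df


def write_cohort(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)


def fit_linreg(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Ordinary least squares y ~ x with slope-t p-value.

    Requires at least 3 paired complete observations and non-degenerate
    x.  A zero-residual fit reports p = 0 with the degeneracy flag set
    (the t statistic is unbounded there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 paired complete observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    fit = sps.linregress(x, y)
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - (fit.intercept + fit.slope * x)) ** 2).sum())
    perfect = sst > 0 and sse <= _PERFECT_FIT_RTOL * sst
    r2 = 1.0 if perfect else (0.0 if sst == 0 else 1.0 - sse / sst)
    p = 0.0 if perfect else float(fit.pvalue)
    return CorrelationResult(
        predictor="x",
        outcome="y",
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        p_value=p,
        q_value=float("nan"),
        n_used=int(n),
        degenerate=perfect,
    )


def correlate_outcomes(
    cohort: pd.DataFrame,
    predictors: Sequence[str] = PREDICTOR_COLUMNS,
    outcomes: Sequence[str] = OUTCOME_COLUMNS,
) -> tuple[list[CorrelationResult], list[tuple[str, str, str]]]:
    """Fit every (predictor, outcome) pair on pairwise-complete data.

    Returns (results, skipped); ``skipped`` lists (predictor, outcome,
    reason) for pairs that failed their preconditions.  q-values are the
    BH step-up values over the family of successfully fitted pairs.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    results: list[CorrelationResult] = []
    skipped: list[tuple[str, str, str]] = []
    for pred in predictors:
        for out in outcomes:
            if pred not in cohort.columns or out not in cohort.columns:
                skipped.append((pred, out, "column missing"))
                continue
            try:
                r = fit_linreg(cohort[pred].to_numpy(float), cohort[out].to_numpy(float))
            except ValueError as exc:
                skipped.append((pred, out, str(exc)))
                continue
            results.append(
                CorrelationResult(
                    predictor=pred,
                    outcome=out,
                    slope=r.slope,
                    intercept=r.intercept,
                    r_squared=r.r_squared,
                    p_value=r.p_value,
                    q_value=float("nan"),
                    n_used=r.n_used,
                    degenerate=r.degenerate,
                )
            )
    if results:
        q = bh_fdr([r.p_value for r in results])
        results = [
            CorrelationResult(
                predictor=r.predictor,
                outcome=r.outcome,
                slope=r.slope,
                intercept=r.intercept,
                r_squared=r.r_squared,
                p_value=r.p_value,
                q_value=float(qi),
                n_used=r.n_used,
                degenerate=r.degenerate,
            )
            for r, qi in zip(results, q)
        ]
    return results, skipped


def sensitivity_exclude_severe(
    cohort: pd.DataFrame,
    volume_field: str = "hemorrhage_volume",
    threshold: float = 5.0,
    predictors: Sequence[str] = PREDICTOR_COLUMNS,
    outcomes: Sequence[str] = OUTCOME_COLUMNS,
) -> tuple[list[CorrelationResult], list[tuple[str, str, str]], int, int]:
    """Re-run the correlation family after excluding severe animals.

    Animals with ``volume_field`` strictly greater than ``threshold``
    (mm³) are removed; animals with a missing volume are retained.
    Returns (results, skipped, n_retained, n_excluded).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    vol = cohort[volume_field].to_numpy(float)
    exclude = vol > threshold  # NaN compares False -> retained
    retained = cohort.loc[~exclude]
    results, skipped = correlate_outcomes(retained, predictors, outcomes)
    return results, skipped, int((~exclude).sum()), int(exclude.sum())


def rout_flag_outliers(
    x: Sequence[float], y: Sequence[float], q_level: float = 0.01
) -> np.ndarray:
    """Simplified ROUT-style outlier flags for a linear relationship.

    A robust line (Theil-Sen, refined by one Tukey-bisquare reweighted
    least-squares pass) is fitted, residuals are scaled by the MAD-based
    robust scale, and points are declared outliers by a BH FDR test on
    two-sided t probabilities of the scaled residuals at ``q_level``.
    This is an approximation of the published ROUT procedure, which is
    specified only as implemented in proprietary software.  Flags are
    advisory: the caller decides what to do with them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 4:
        raise ValueError("need >= 4 paired observations")
    flags = np.zeros(x.size, dtype=bool)
    if q_level <= 0:
        return flags
    xi, yi = x[keep], y[keep]
    slope, intercept, _, _ = sps.theilslopes(yi, xi)
    resid = yi - (intercept + slope * xi)
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if scale > 0:
        # one bisquare reweighting pass to pull the line off any gross outlier
        u = resid / (4.685 * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() > 0 and np.ptp(xi[w > 0]) > 0:
            W = np.diag(w)
            A = np.column_stack([np.ones_like(xi), xi])
            beta, *_ = np.linalg.lstsq(np.sqrt(W) @ A, np.sqrt(w) * yi, rcond=None)
            intercept, slope = beta
            resid = yi - (intercept + slope * xi)
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if scale <= 0:
        return flags  # (near-)perfect fit: nothing to flag
    t = resid / scale
    p = 2.0 * sps.t.sf(np.abs(t), df=max(xi.size - 2, 1))
    q = bh_fdr(p)
    flags[keep] = q < q_level
    return flags
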