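"""Test-retest reliability: ICC(2,k), SEM, MDC95 and interpretation bands.

The average-measures absolute-agreement intraclass correlation is computed
from the two-way ANOVA mean squares,

    ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n),

with the usual F-based 95% confidence interval (single-measures bounds with
a Satterthwaite denominator df, stepped up to average measures by the
Spearman-Brown relation).  The label "two-way mixed effects with absolute
agreement" and the ICC(2,k) notation denote numerically identical
average-measures absolute-agreement coefficients, so a single formula
serves both.  Negative ICC values (and negative CI bounds) are admissible
and returned as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats

from .core import ScapkinError

#: MDC95 multiplier: sqrt(2) * 1.96.
MDC95_FACTOR = float(np.sqrt(2.0) * 1.96)

#: Interpretation cut-points: little < 0.16 <= low < 0.50 <= moderate
#: < 0.70 <= high < 0.90 <= very high.  The verbal scale as usually quoted
#: leaves the gaps 0.15-0.16, 0.49-0.50, 0.69-0.70 and the point 0.90
#: unassigned; this convention closes them at the upper bound of each band.
_BANDS = ((0.16, "little"), (0.50, "low"), (0.70, "moderate"),
          (0.90, "high"), (np.inf, "very high"))


@dataclass(frozen=True)
class ReliabilityResult:
    """Reliability summary for one outcome."""

    outcome: str
    icc: float
    ci95: tuple[float, float]
    sem: float
    mdc95: float
    band: str


def icc_2k(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Average-measures absolute-agreement ICC with its confidence interval.

    ``ratings`` is a subjects x measurements matrix with no missing cells.
    Zero between-subject variance is not an error: the ICC may then be <= 0.
    The raw ANOVA ratio is returned unclamped; in pathological small
    samples (tiny or negative denominator) it can fall outside the usual
    (-inf, 1] range, which is a property of the estimator, not a bug.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ScapkinError("ratings must be a 2-D subjects x measurements array")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ScapkinError(f"need >= 2 subjects and >= 2 measurements, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ScapkinError("ratings contain missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else np.nan

    if mse <= 0:  # degenerate: identical columns -> perfect agreement
        return float(icc), (float(icc), float(icc))

    # Single-measures absolute-agreement CI (F-based, Satterthwaite df),
    # then Spearman-Brown step-up to average measures.
    icc1_denom = msr + (k - 1) * mse + k * (msc - mse) / n
    r1 = (msr - mse) / icc1_denom if icc1_denom != 0 else np.nan
    a = k * r1 / (n * (1.0 - r1)) if r1 < 1 else np.inf
    b = 1.0 + k * r1 * (n - 1) / (n * (1.0 - r1)) if r1 < 1 else np.inf
    with np.errstate(invalid="ignore", divide="ignore"):
        num_v = (a * msc + b * mse) ** 2
        den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v if den_v > 0 else 1.0
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi1 = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr)

    def step_up(r: float) -> float:
        denom_sb = 1.0 + (k - 1) * r
        return k * r / denom_sb if denom_sb != 0 else -np.inf

    lo, hi = step_up(lo1), step_up(hi1)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        # degenerate sample: the F-based interval is undefined
        point = float(min(icc, 1.0))
        return float(icc), (point, point)
    if lo > hi:
        # The Spearman-Brown step-up has a pole at r = -1/(k-1); when a
        # degenerate (pure-noise) sample pushes a single-measures bound
        # across it the mapped interval wraps.  Report a sane interval.
        lo, hi = min(lo, hi), min(max(lo, hi), 1.0)
    return float(icc), (float(lo), float(hi))


def sem(sd: float, icc: float) -> float:
    """Standard error of measurement, SD * sqrt(1 - ICC).

    ICC < 0 is permitted (the radicand then exceeds 1); ICC must be <= 1.
    """
    if sd < 0:
        raise ScapkinError("sd must be >= 0")
    if icc > 1:
        raise ScapkinError("icc must be <= 1")
    return sd * sqrt(1.0 - icc)


def mdc95(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence, SEM * sqrt(2) * 1.96."""
    if sem_value < 0:
        raise ScapkinError("sem must be >= 0")
    return sem_value * MDC95_FACTOR


def reliability_band(icc: float) -> str:
    """Verbal interpretation of an ICC value."""
    if not np.isfinite(icc):
        raise ScapkinError("icc must be finite")
    for upper, label in _BANDS:
        if icc < upper:
            return label
    raise AssertionError("unreachable")


def reliability_result(outcome: str, ratings: np.ndarray,
                       sd_source: str = "first") -> ReliabilityResult:
    """Full reliability summary for one outcome from repeated measurements.

    ``sd_source`` selects the SD entering the SEM: ``"first"`` uses the
    between-subject SD of the first measurement column, ``"pooled"`` the SD
    of all cells around their column means combined with the
    between-subject spread (i.e. the SD of the flattened matrix).
    """
    x = np.asarray(ratings, dtype=float)
    icc, ci = icc_2k(x)
    if sd_source == "first":
        sd = float(np.std(x[:, 0], ddof=1))
    elif sd_source == "pooled":
        sd = float(np.std(x.ravel(), ddof=1))
    else:
        raise ScapkinError(f"unknown sd_source {sd_source!r}")
    s = sem(sd, min(icc, 1.0))
    return ReliabilityResult(outcome=outcome, icc=icc, ci95=ci, sem=s,
                             mdc95=mdc95(s), band=reliability_band(icc))
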