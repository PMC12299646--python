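"""Pre-post inference: normality-gated paired tests, effect sizes, power.

Test selection is gated per outcome by a Shapiro-Wilk test on the paired
differences (p >= 0.05 -> paired t, else Wilcoxon signed-rank); the
protocol's additional visual histogram inspection is out of scope and a
flag marks gated decisions accordingly.  No multiple-comparison adjustment
is applied by default, mirroring the unadjusted reporting convention of
single-group exploratory designs; a Holm step-down correction is available
as an opt-in on the results table.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .core import ScapkinError

def effect_size_band(d: float) -> str:
    """Verbal band for Cohen's d: < 0.2 small, around 0.5 (up to 0.8)
    moderate, > 0.8 large."""
    a = abs(d)
    if a < 0.2:
        return "small"
    if a <= 0.8:
        return "moderate"
    return "large"


@dataclass(frozen=True)
class GateResult:
    branch: str            # "parametric" | "nonparametric"
    shapiro_p: float
    zero_variance: bool
    visual_inspection_done: bool = False


@dataclass(frozen=True)
class PrePostResult:
    """Paired comparison of one outcome between sessions M0 and M1."""

    outcome: str
    test: str              # "paired_t" | "wilcoxon"
    statistic: float
    p: float
    effect_size: float | None      # Cohen's d, parametric branch only
    difference: float              # mean (t) or median (Wilcoxon) of M1 - M0
    m0_descriptive: tuple[float, float]
    m1_descriptive: tuple[float, float]
    descriptive_kind: str          # "mean±SD" | "median±IQR"
    gate: GateResult


def normality_gate(differences: np.ndarray, alpha: float = 0.05) -> GateResult:
    """Shapiro-Wilk gate on the paired differences.

    Constant differences make the test undefined; they are routed to the
    nonparametric branch with a zero-variance flag.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ScapkinError(f"need >= 3 paired differences, got {d.size}")
    if np.ptp(d) == 0.0:
        return GateResult("nonparametric", np.nan, zero_variance=True)
    p = float(stats.shapiro(d).pvalue)
    return GateResult("parametric" if p >= alpha else "nonparametric", p,
                      zero_variance=False)


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design effect size d = t / sqrt(n)."""
    if n < 2:
        raise ScapkinError("need n >= 2")
    return t / sqrt(n)


def effect_size_from_mcid(mcid: float, sd: float) -> float:
    """Design-stage effect size d = MCID / SD."""
    if sd <= 0:
        raise ScapkinError("sd must be > 0")
    return mcid / sd


def summarize(values: np.ndarray, branch: str) -> tuple[float, float]:
    """(mean, SD) for the parametric branch, (median, IQR) otherwise.

    The IQR uses linearly interpolated (type-7) quartiles.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ScapkinError("empty input")
    if branch == "parametric":
        if x.size < 2:
            raise ScapkinError("SD undefined for a single value")
        return float(np.mean(x)), float(np.std(x, ddof=1))
    q1, q3 = np.percentile(x, [25, 75])
    return float(np.median(x)), float(q3 - q1)


def paired_compare(m0: np.ndarray, m1: np.ndarray,
                   outcome: str = "", alpha: float = 0.05) -> PrePostResult:
    """Paired pre-post comparison with normality-gated test selection.

    Parametric branch: paired t-test, Cohen's d = t / sqrt(n), mean +/- SD
    descriptives, mean difference.  Nonparametric branch: Wilcoxon
    signed-rank with Pratt handling of zero differences, median +/- IQR
    descriptives, median difference; no effect size is reported.
    """
    x0 = np.asarray(m0, dtype=float)
    x1 = np.asarray(m1, dtype=float)
    if x0.shape != x1.shape:
        raise ScapkinError(f"length mismatch: {x0.shape} vs {x1.shape}")
    if x0.size < 3:
        raise ScapkinError("need >= 3 paired observations")
    diffs = x1 - x0
    gate = normality_gate(diffs, alpha=alpha)

    if gate.branch == "parametric":
        res = stats.ttest_rel(x1, x0)
        t = float(res.statistic)
        return PrePostResult(
            outcome=outcome, test="paired_t", statistic=t,
            p=float(res.pvalue), effect_size=cohens_d_from_t(t, x0.size),
            difference=float(np.mean(diffs)),
            m0_descriptive=summarize(x0, "parametric"),
            m1_descriptive=summarize(x1, "parametric"),
            descriptive_kind="mean±SD", gate=gate,
        )
    if gate.zero_variance and np.all(diffs == 0.0):
        stat, p = np.nan, 1.0
    else:
        stat_res = stats.wilcoxon(x1, x0, zero_method="pratt")
        stat, p = float(stat_res.statistic), float(stat_res.pvalue)
    return PrePostResult(
        outcome=outcome, test="wilcoxon", statistic=stat, p=p,
        effect_size=None, difference=float(np.median(diffs)),
        m0_descriptive=summarize(x0, "nonparametric"),
        m1_descriptive=summarize(x1, "nonparametric"),
        descriptive_kind="median±IQR", gate=gate,
    )


@dataclass(frozen=True)
class PowerSpec:
    """Design-stage power analysis specification for a paired t-test."""

    d: float
    alpha: float = 0.05
    power: float = 0.8
    tails: str = "one"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ScapkinError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ScapkinError("power must be in (0, 1)")
        if self.tails not in ("one", "two"):
            raise ScapkinError("tails must be 'one' or 'two'")


def paired_t_power(n: int, spec: PowerSpec) -> float:
    """Power of the paired t-test at sample size ``n`` from the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = spec.d * sqrt(n)
    if spec.tails == "one":
        t_crit = stats.t.ppf(1 - spec.alpha, df)
        return float(1 - stats.nct.cdf(t_crit, df, ncp))
    t_crit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float((1 - stats.nct.cdf(t_crit, df, ncp))
                 + stats.nct.cdf(-t_crit, df, ncp))


def required_sample_size(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest n whose paired t-test attains the requested power."""
    if spec.d <= 0:
        raise ScapkinError("effect size d must be > 0")
    for n in range(2, n_max + 1):
        if paired_t_power(n, spec) >= spec.power:
            return n
    raise ScapkinError(f"no n <= {n_max} reaches power {spec.power}")


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (optional, off by default upstream)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def prepost_table(m0: pd.DataFrame, m1: pd.DataFrame,
                  adjust: str = "none") -> pd.DataFrame:
    """Paired comparisons for every shared outcome column.

    ``m0``/``m1`` are subjects x outcomes frames with matching indices.
    """
    if adjust not in ("none", "holm"):
        raise ScapkinError(f"unknown adjustment {adjust!r}")
    if list(m0.index) != list(m1.index):
        raise ScapkinError("M0 and M1 must cover the same subjects in order")
    rows = []
    for col in m0.columns:
        r = paired_compare(m0[col].to_numpy(), m1[col].to_numpy(), outcome=col)
        rows.append({
            "outcome": col, "test": r.test, "statistic": r.statistic,
            "p": r.p, "effect_size": r.effect_size,
            "difference": r.difference,
            "m0_center": r.m0_descriptive[0], "m0_spread": r.m0_descriptive[1],
            "m1_center": r.m1_descriptive[0], "m1_spread": r.m1_descriptive[1],
            "descriptive": r.descriptive_kind, "shapiro_p": r.gate.shapiro_p,
        })
    table = pd.DataFrame(rows)
    if adjust == "holm":
        table["p_adjusted"] = holm_adjust(table["p"].to_numpy())
    return table
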