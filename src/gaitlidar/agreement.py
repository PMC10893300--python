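"""Method-agreement statistics between two measurement systems.

Given paired per-walk gait parameters from two systems (e.g., a lidar
pipeline and a pressure-sensitive walkway, or a pipeline and simulation
ground truth), this module provides the classical comparison battery:
paired t-tests with Cohen's d, simple linear regression validated by an
F-test, Pearson correlation with error metrics and a 95% confidence
interval of the mean difference, and Bland–Altman limits of agreement.

Sample (n-1) standard deviations are used throughout.  The default
significance level is alpha = 0.01; p-values compared across several
parameters can be Bonferroni-adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "paired_test",
    "regression_agreement",
    "bland_altman",
    "bland_altman_plot",
    "bonferroni",
    "correlation_strength",
    "compare_systems",
]

ALPHA = 0.01

#: Qualitative correlation labels (Schober-style interpretation bands).
_CORRELATION_BANDS = [
    (0.9, "very strong"),
    (0.7, "strong"),
    (0.4, "moderate"),
    (0.1, "weak"),
    (0.0, "negligible"),
]


@dataclass
class PairedSeries:
    """Equal-length paired measurements of one parameter from two systems."""

    name: str
    a: np.ndarray
    b: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be equal-length 1D arrays")
        if self.a.size < 3:
            raise ValueError("need at least three pairs")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return int(self.a.size)

    @property
    def diff(self) -> np.ndarray:
        return self.b - self.a


@dataclass
class AgreementReport:
    parameter: str
    n: int
    t: float
    p: float
    dof: int
    cohen_d: float
    slope: float
    intercept: float
    r2: float
    f_stat: float
    pearson_r: float
    mean_diff: float
    se: float
    rmse: float
    ci95: tuple[float, float]
    bland_altman: tuple[float, float, float]  # bias, loa_lower, loa_upper
    correlation_label: str


def paired_test(s: PairedSeries) -> tuple[float, float, int, float]:
    """Classical paired two-sample t-test on the differences.

    Returns ``(t, p, dof, cohen_d)`` with ``dof = n - 1`` and Cohen's
    d = |mean difference| / sd of differences.  Zero-variance differences
    with a nonzero mean yield an infinite t (p = 0), flagged rather than
    raised.
    """
    d = s.diff
    n = s.n
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    dof = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, dof, 0.0
        return math.copysign(math.inf, mean), 0.0, dof, math.inf
    t = mean / (sd / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), dof)
    cohen_d = abs(mean) / sd
    return float(t), float(p), dof, float(cohen_d)


def regression_agreement(s: PairedSeries):
    """Simple linear regression of system B on system A, plus error metrics.

    Returns ``(slope, intercept, r2, f_stat, pearson_r, mean_diff, se,
    rmse, ci95)``.  The F statistic tests the regression against the
    intercept-only model; ``se`` is the standard error of the mean
    difference and ``ci95`` the t-based 95% confidence interval around it.
    """
    a, b, n = s.a, s.b, s.n
    if np.std(a) == 0:
        raise ValueError("system A values are constant; regression undefined")
    am, bm = a.mean(), b.mean()
    sxx = float(np.sum((a - am) ** 2))
    sxy = float(np.sum((a - am) * (b - bm)))
    slope = sxy / sxx
    intercept = bm - slope * am
    fitted = intercept + slope * a
    ss_res = float(np.sum((b - fitted) ** 2))
    ss_tot = float(np.sum((b - bm) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if ss_res == 0:
        f_stat = math.inf
    else:
        f_stat = (ss_tot - ss_res) / (ss_res / (n - 2))
    sy = float(np.std(b, ddof=1))
    sx = float(np.std(a, ddof=1))
    pearson_r = slope * sx / sy if sy > 0 else (1.0 if ss_res == 0 else 0.0)

    d = s.diff
    mean_diff = float(np.mean(d))
    rmse = float(np.sqrt(np.mean(d**2)))
    se = float(np.std(d, ddof=1) / math.sqrt(n))
    tcrit = stats.t.ppf(0.975, n - 1)
    ci95 = (mean_diff - tcrit * se, mean_diff + tcrit * se)
    return slope, intercept, r2, f_stat, pearson_r, mean_diff, se, rmse, ci95


def bland_altman(s: PairedSeries):
    """Bias and 95% limits of agreement of the paired differences.

    Returns ``(bias, loa_lower, loa_upper, means, diffs)``; the per-pair
    means and differences are the Bland–Altman plot coordinates.
    """
    d = s.diff
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = 1.96 * sd
    means = 0.5 * (s.a + s.b)
    return bias, bias - loa, bias + loa, means, d


def bland_altman_plot(s: PairedSeries, ax=None):
    """Draw the Bland–Altman plot: per-pair differences against means, with
    the bias line and the 95% limits of agreement."""
    import matplotlib.pyplot as plt

    bias, lo, hi, means, diffs = bland_altman(s)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(means, diffs, s=12, alpha=0.7)
    ax.axhline(bias, color="k", lw=1)
    for y in (lo, hi):
        ax.axhline(y, color="k", lw=1, ls="--")
    unit = f" ({s.unit})" if s.unit else ""
    ax.set_xlabel(f"mean of systems{unit}")
    ax.set_ylabel(f"difference (B - A){unit}")
    ax.set_title(s.name)
    return ax


def bonferroni(p_values, alpha: float = ALPHA):
    """Bonferroni-adjusted p-values (clipped at 1) and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    adjusted = np.minimum(p * p.size, 1.0)
    return adjusted, adjusted <= alpha


def correlation_strength(r: float) -> str:
    """Qualitative label for a correlation magnitude."""
    for threshold, label in _CORRELATION_BANDS:
        if abs(r) >= threshold:
            return label
    return "negligible"


def compare_systems(s: PairedSeries) -> AgreementReport:
    """Run the full agreement battery on one paired parameter series."""
    t, p, dof, d = paired_test(s)
    slope, intercept, r2, f_stat, r, mean_diff, se, rmse, ci95 = (
        regression_agreement(s)
    )
    bias, lo, hi, _, _ = bland_altman(s)
    return AgreementReport(
        parameter=s.name, n=s.n, t=t, p=p, dof=dof, cohen_d=d,
        slope=slope, intercept=intercept, r2=r2, f_stat=f_stat,
        pearson_r=r, mean_diff=mean_diff, se=se, rmse=rmse, ci95=ci95,
        bland_altman=(bias, lo, hi),
        correlation_label=correlation_strength(r),
    )
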