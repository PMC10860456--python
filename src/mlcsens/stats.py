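"""Sensitivity slopes, group comparisons, correlations and tolerances.

The dose-error response is summarized per case and structure as the
ordinary-least-squares slope of gEUD change versus error magnitude (%/mm
for targets, Gy/mm for OARs), fit separately for the closing and opening
directions with the zero-error point included.  The MLC tolerance for a
scenario is the largest positional error that keeps the target's gEUD
change within a threshold (default +/-2%), i.e. threshold divided by the
worse of the two directional slopes, aggregated over cases.

Hypothesis tests follow a Shapiro-Wilk normality gate at alpha = 0.05:
normal samples get a t-test / Pearson correlation, otherwise the Wilcoxon
signed-rank test / Spearman correlation.  Correlation strength bands:
|r| <= 0.2 zero, (0.2, 0.4] weak, (0.4, 0.7] moderate, > 0.7 strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["SensitivityResult", "ToleranceResult", "StatComparison",
           "CorrelationResult", "fit_sensitivity", "derive_tolerance",
           "compare_groups", "correlate", "strength_band"]

ALPHA = 0.05


@dataclass(frozen=True)
class SensitivityResult:
    case_id: str
    structure: str
    slope: float          # %/mm for targets, Gy/mm for OARs (sign retained)
    intercept: float
    r: float              # correlation coefficient of the linear fit
    direction: str        # close | open | combined
    units: str            # "%/mm" or "Gy/mm"


@dataclass(frozen=True)
class ToleranceResult:
    scenario: str
    tolerance_mm: float
    threshold_pct: float
    n_cases: int
    n_unbounded: int      # cases with zero slope (excluded from the aggregate)
    aggregation: str


@dataclass(frozen=True)
class StatComparison:
    normality_p: tuple[float, float]
    test_used: str        # t_test | wilcoxon_signed_rank
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class CorrelationResult:
    x_metric: str
    y_metric: str
    method: str           # pearson | spearman
    coefficient: float
    p_value: float

    @property
    def strength_band(self) -> str:
        return strength_band(self.coefficient)


def strength_band(coefficient: float) -> str:
    c = abs(coefficient)
    if c <= 0.2:
        return "zero"
    if c <= 0.4:
        return "weak"
    if c <= 0.7:
        return "moderate"
    return "strong"


def fit_sensitivity(points, direction: str, case_id: str = "",
                    structure: str = "target", units: str = "%/mm") -> SensitivityResult:
    """OLS slope of gEUD change versus error magnitude.

    ``points`` are (error_mm, delta) pairs; include (0, 0) so the fit is
    anchored at the unperturbed plan.  For a perfectly flat response the fit
    correlation is reported as 0.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or np.unique(pts[:, 0]).size < 2:
        raise ValueError("need >= 2 points with distinct error magnitudes")
    x, y = pts[:, 0], pts[:, 1]
    if np.allclose(y, y[0]):
        slope, intercept, r = 0.0, float(y[0]), 0.0
    else:
        res = sps.linregress(x, y)
        slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    return SensitivityResult(case_id, structure, slope, intercept, r, direction, units)


def derive_tolerance(sensitivities, threshold_pct: float = 2.0,
                     scenario: str = "", aggregation: str = "mean") -> ToleranceResult:
    """Largest error (mm) keeping |gEUD change| within ``threshold_pct``.

    Per case the tolerance is threshold / max(|close slope|, |open slope|);
    the scenario value aggregates per-case tolerances (mean by default,
    ``median`` and ``min`` available).  Cases whose slopes are all zero have
    an unbounded tolerance: they are counted and excluded.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be > 0")
    by_case: dict[str, float] = {}
    for s in sensitivities:
        by_case[s.case_id] = max(by_case.get(s.case_id, 0.0), abs(s.slope))
    if not by_case:
        raise ValueError("no sensitivities supplied")
    tols = [threshold_pct / m for m in by_case.values() if m > 0]
    n_unbounded = len(by_case) - len(tols)
    if not tols:
        raise ValueError("all cases have zero slope; tolerance unbounded")
    agg = {"mean": np.mean, "median": np.median, "min": np.min}[aggregation]
    return ToleranceResult(scenario, float(agg(tols)), threshold_pct,
                           len(by_case), n_unbounded, aggregation)


def _shapiro_p(x: np.ndarray) -> float:
    if np.allclose(x, x[0]):
        return 1.0   # a degenerate constant sample cannot reject normality here
    return float(sps.shapiro(x).pvalue)


def compare_groups(a, b, paired: bool = True) -> StatComparison:
    """Shapiro-Wilk-gated two-sample comparison at alpha = 0.05."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 observations per group")
    if paired and a.size != b.size:
        raise ValueError("paired samples must have equal length")
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    normal = pa >= ALPHA and pb >= ALPHA
    if paired:
        diff = a - b
        if np.allclose(diff, 0.0):
            return StatComparison((pa, pb), "t_test" if normal else
                                  "wilcoxon_signed_rank", 1.0)
        if normal:
            p = float(sps.ttest_rel(a, b).pvalue)
            test = "t_test"
        else:
            p = float(sps.wilcoxon(a, b).pvalue)
            test = "wilcoxon_signed_rank"
    else:
        if normal:
            p = float(sps.ttest_ind(a, b).pvalue)
            test = "t_test"
        else:
            p = float(sps.mannwhitneyu(a, b).pvalue)
            test = "wilcoxon_signed_rank"
    return StatComparison((pa, pb), test, p)


def correlate(x, y, x_metric: str = "x", y_metric: str = "y") -> CorrelationResult:
    """Normality-gated correlation: Pearson when both samples pass Shapiro-Wilk."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with >= 3 observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for a constant sample")
    if _shapiro_p(x) >= ALPHA and _shapiro_p(y) >= ALPHA:
        res = sps.pearsonr(x, y)
        method = "pearson"
    else:
        res = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(x_metric, y_metric, method,
                             float(res.statistic), float(res.pvalue))
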