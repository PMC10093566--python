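"""ROC analysis and diagnostic-performance metrics for node-level features.

All tests are oriented so that larger feature values indicate malignancy and
positivity is the inclusive rule ``value >= threshold``, matching the score
conditions used throughout the package.  The optimal cut-off is the operating
point closest to the ideal corner (sensitivity 1, specificity 1):

    d = sqrt((1 - sensitivity)^2 + (1 - specificity)^2)

The AUC point estimate is the trapezoidal area under the empirical ROC curve,
which equals the rank-sum (concordance) statistic with ties counted 1/2.  The
default 95% confidence interval uses DeLong's placement-based variance
estimator; the Hanley-McNeil exponential approximation is available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import numpy as np
from scipy import stats

from .cohort import ContingencyTable, _as_bool_labels, build_contingency

__all__ = [
    "ROCCurve",
    "AUCEstimate",
    "CutoffResult",
    "PerformanceMetrics",
    "roc_curve",
    "auc",
    "optimal_cutoff",
    "metrics_from_contingency",
    "compare_groups",
    "round_half_up",
]


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve: one operating point per distinct threshold.

    ``thresholds`` are sorted ascending; positivity at threshold ``t`` is
    ``value >= t``.  A synthetic ``+inf`` threshold supplies the degenerate
    (sensitivity 0, specificity 1) endpoint; the smallest observed value gives
    (sensitivity 1, specificity 0) since every value tests positive there.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_malignant: int
    n_benign: int

    def __len__(self) -> int:
        return len(self.thresholds)

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivity

    def operating_points(self):
        """Iterate (threshold, sensitivity, specificity) triples."""
        return list(zip(self.thresholds, self.sensitivity, self.specificity))


@dataclass(frozen=True)
class AUCEstimate:
    """Area under the ROC curve with a 95% confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "delong"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0):
            raise ValueError(
                f"inconsistent AUC estimate: ci_low={self.ci_low}, auc={self.auc}, ci_high={self.ci_high}"
            )


@dataclass(frozen=True)
class CutoffResult:
    """The ROC operating point closest to the (0, 1) corner."""

    threshold: float
    d: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        expected = float(np.hypot(1.0 - self.sensitivity, 1.0 - self.specificity))
        if abs(self.d - expected) > 1e-12:
            raise ValueError("d must equal sqrt((1-sens)^2 + (1-spec)^2) at the operating point")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as conventional in clinical reporting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy of one 2x2 table.

    Raw fractions are kept unrounded; ``as_percentages`` formats them the way
    clinical tables print them (x100, two decimals, half-up).  A metric whose
    denominator is empty is ``None`` (explicitly undefined, never 0).
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float

    def as_percentages(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            name: (None if v is None else round_half_up(100.0 * v, ndigits))
            for name, v in [
                ("sensitivity", self.sensitivity), ("specificity", self.specificity),
                ("ppv", self.ppv), ("npv", self.npv), ("accuracy", self.accuracy),
            ]
        }


def _prepare(values: Iterable[float], labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(list(values), dtype=float)
    lab = _as_bool_labels(labels)
    if v.size != lab.size:
        raise ValueError(f"values ({v.size}) and labels ({lab.size}) differ in length")
    if v.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("feature values must be finite")
    if lab.all() or not lab.any():
        raise ValueError("both histology classes must be present for ROC analysis")
    return v, lab


def roc_curve(values: Iterable[float], labels) -> ROCCurve:
    """Empirical ROC curve with inclusive (>=) thresholds.

    One operating point per distinct observed value, plus the degenerate
    (sens 0, spec 1) endpoint at threshold ``+inf``.
    """
    v, lab = _prepare(values, labels)
    n_pos = int(lab.sum())
    n_neg = int(v.size - n_pos)

    thresholds = np.unique(v)  # ascending
    # Cumulative counts: positives/negatives with value >= t.
    order = np.argsort(v, kind="mergesort")
    v_sorted = v[order]
    lab_sorted = lab[order]
    # For each threshold, index of first element >= t.
    idx = np.searchsorted(v_sorted, thresholds, side="left")
    pos_cum = np.concatenate([np.cumsum(lab_sorted[::-1])[::-1], [0]])
    neg_cum = np.concatenate([np.cumsum((~lab_sorted)[::-1])[::-1], [0]])
    tp = pos_cum[idx]
    fp = neg_cum[idx]
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg

    thresholds = np.concatenate([thresholds, [np.inf]])
    sens = np.concatenate([sens, [0.0]])
    spec = np.concatenate([spec, [1.0]])
    return ROCCurve(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        n_malignant=n_pos, n_benign=n_neg,
    )


def _auc_point(v: np.ndarray, lab: np.ndarray) -> float:
    """Trapezoidal AUC; equals pairwise concordance with ties counted 1/2."""
    curve = roc_curve(v, lab)
    fpr = curve.fpr
    tpr = curve.tpr
    # Proper staircase: ascending FPR, ties ordered by TPR so tied-FPR
    # points form vertical segments that contribute no area.
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def _delong_variance(v: np.ndarray, lab: np.ndarray, a: float) -> float:
    x = v[lab]      # malignant
    y = v[~lab]     # benign
    m, n = x.size, y.size
    # Placements via midranks (handles ties with the 1/2 convention).
    all_ranks = stats.rankdata(np.concatenate([x, y]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    v10 = (all_ranks[:m] - rx) / n          # P(Y < x_i) + 0.5 P(Y = x_i)
    v01 = 1.0 - (all_ranks[m:] - ry) / m    # P(x > y_j) + 0.5 ties
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _hanley_mcneil_variance(m: int, n: int, a: float) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    return (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)


def auc(values: Iterable[float], labels, method: str = "delong", level: float = 0.95) -> AUCEstimate:
    """AUC point estimate with a Wald confidence interval.

    Parameters
    ----------
    method:
        ``"delong"`` (default) for the placement-based DeLong variance, or
        ``"hanley-mcneil"`` for the exponential approximation.
    """
    v, lab = _prepare(values, labels)
    a = _auc_point(v, lab)
    m = int(lab.sum())
    n = int(v.size - m)
    if method == "delong":
        var = _delong_variance(v, lab, a)
    elif method in ("hanley-mcneil", "hanley_mcneil"):
        var = _hanley_mcneil_variance(m, n, a)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = float(np.sqrt(max(var, 0.0)))
    lo = min(a, max(0.0, a - z * se))
    hi = max(a, min(1.0, a + z * se))
    return AUCEstimate(auc=a, ci_low=lo, ci_high=hi, level=level, method=method)


def optimal_cutoff(curve: ROCCurve) -> CutoffResult:
    """Operating point minimizing the Euclidean distance to (sens 1, spec 1).

    Ties are broken in favor of higher specificity, then lower threshold.
    The synthetic +inf endpoint is not a candidate (it is not an observed
    threshold); a curve with no finite operating point is rejected.
    """
    finite = np.isfinite(curve.thresholds)
    if not finite.any():
        raise ValueError("degenerate ROC curve: no finite operating point")
    thr = curve.thresholds[finite]
    sens = curve.sensitivity[finite]
    spec = curve.specificity[finite]
    d = np.hypot(1.0 - sens, 1.0 - spec)
    # Lexicographic: smallest d, then highest specificity, then lowest threshold.
    best = min(range(len(thr)), key=lambda i: (d[i], -spec[i], thr[i]))
    return CutoffResult(
        threshold=float(thr[best]), d=float(d[best]),
        sensitivity=float(sens[best]), specificity=float(spec[best]),
    )


def metrics_from_contingency(t: ContingencyTable) -> PerformanceMetrics:
    """Standard operating characteristics of a 2x2 table (raw fractions).

    A metric with an empty denominator (e.g. PPV with no positive calls) is
    returned as ``None``.
    """

    def frac(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return PerformanceMetrics(
        sensitivity=frac(t.tp, t.tp + t.fn),
        specificity=frac(t.tn, t.tn + t.fp),
        ppv=frac(t.tp, t.tp + t.fp),
        npv=frac(t.tn, t.tn + t.fn),
        accuracy=(t.tp + t.tn) / t.n,
    )


def roc_point_from_values(values, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the inclusive test at one threshold."""
    t = build_contingency(values, labels, threshold)
    m = metrics_from_contingency(t)
    return m.sensitivity, m.specificity


def compare_groups(benign_values: Iterable[float], malignant_values: Iterable[float]) -> float:
    """Two-sided Mann-Whitney U p-value comparing the class distributions.

    Uses the asymptotic normal approximation with tie correction and
    continuity correction; two identical groups give p = 1.0.
    """
    b = np.asarray(list(benign_values), dtype=float)
    m = np.asarray(list(malignant_values), dtype=float)
    if b.size == 0 or m.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([b, m])
    if np.all(pooled == pooled[0]):
        return 1.0  # every observation tied: no evidence of a shift
    res = stats.mannwhitneyu(b, m, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
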