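"""Diagnostic-test-accuracy statistics.

Confusion tables, the four proportions with exact (Clopper-Pearson)
confidence intervals, ROC/AUROC with Wald limits, three cut-off selection
rules, prevalence, dual-adjudication merging and the sensitivity-driven
sample-size formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionTable",
    "MetricEstimate",
    "ROCPoint",
    "ROCCurve",
    "AUROCEstimate",
    "CutoffSelection",
    "SampleSizeSpec",
    "AlignmentError",
    "UndefinedMetricError",
    "build_confusion",
    "metric",
    "all_metrics",
    "clopper_pearson",
    "roc_curve",
    "auroc",
    "select_cutoff_constrained",
    "select_cutoff_youden",
    "select_cutoff_sens_eq_spec",
    "sample_size_sensitivity",
    "prevalence",
    "merge_adjudications",
]

METRICS = ("sensitivity", "specificity", "ppv", "npv")


class AlignmentError(ValueError):
    """Calls and truth labels do not cover the same record ids."""


class UndefinedMetricError(ZeroDivisionError):
    """The metric's denominator is zero (e.g. PPV with no positive calls)."""


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion table must contain at least one record")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def numerator_denominator(self, which: str) -> tuple[int, int]:
        if which == "sensitivity":
            return self.tp, self.tp + self.fn
        if which == "specificity":
            return self.tn, self.tn + self.fp
        if which == "ppv":
            return self.tp, self.tp + self.fp
        if which == "npv":
            return self.tn, self.tn + self.fn
        raise ValueError(f"unknown metric {which!r}")


@dataclass(frozen=True)
class MetricEstimate:
    metric: str
    point: float
    ci_low: float
    ci_high: float
    x: int
    n: int
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 <= self.ci_low <= self.point <= self.ci_high <= 1):
            raise ValueError("interval must satisfy ci_low <= point <= ci_high in [0,1]")

    @property
    def percent(self) -> float:
        """Point estimate on the 0-100 scale, rounded to 1 dp."""
        return round(100 * self.point, 1)


def build_confusion(calls: dict[str, bool], truth: dict[str, bool]) -> ConfusionTable:
    """Cross-tabulate call-positive against truth-positive per record id."""
    if not calls or not truth:
        raise AlignmentError("calls and truth must both be non-empty")
    only_calls = sorted(set(calls) - set(truth))
    only_truth = sorted(set(truth) - set(calls))
    if only_calls or only_truth:
        raise AlignmentError(
            f"unmatched ids: calls-only={only_calls[:10]} truth-only={only_truth[:10]}"
        )
    tp = fp = fn = tn = 0
    for rid, called in calls.items():
        if called and truth[rid]:
            tp += 1
        elif called:
            fp += 1
        elif truth[rid]:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp, fp, fn, tn)


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial interval via beta-distribution quantiles."""
    if not 0 <= x <= n or n <= 0:
        raise ValueError("require 0 <= x <= n, n > 0")
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def metric(table: ConfusionTable, which: str, alpha: float = 0.05) -> MetricEstimate:
    """One of sensitivity/specificity/ppv/npv with its exact CI."""
    x, n = table.numerator_denominator(which)
    if n == 0:
        raise UndefinedMetricError(f"{which} undefined: denominator is zero")
    low, high = clopper_pearson(x, n, alpha)
    return MetricEstimate(which, x / n, low, high, x, n, alpha)


def all_metrics(table: ConfusionTable, alpha: float = 0.05) -> dict[str, MetricEstimate]:
    """All four metrics; undefined ones are omitted (the '-' table cells)."""
    out = {}
    for which in METRICS:
        try:
            out[which] = metric(table, which, alpha)
        except UndefinedMetricError:
            pass
    return out


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    tpr: float
    fpr: float
    table: ConfusionTable


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[ROCPoint, ...]
    n_pos: int
    n_neg: int


def _split_scores(scores: dict[str, float], truth: dict[str, bool]):
    if set(scores) != set(truth):
        raise AlignmentError("scores and truth must cover identical ids")
    pos = np.array([s for rid, s in scores.items() if truth[rid]], dtype=float)
    neg = np.array([s for rid, s in scores.items() if not truth[rid]], dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    return pos, neg


def roc_curve(scores: dict[str, float], truth: dict[str, bool]) -> ROCCurve:
    """One point per distinct observed score (call-positive iff score >= t)
    plus a sentinel threshold above the maximum (the all-negative corner)."""
    pos, neg = _split_scores(scores, truth)
    n_pos, n_neg = len(pos), len(neg)
    thresholds = sorted(set(scores.values()))
    thresholds.append(max(thresholds) + 1.0)  # sentinel: nothing called
    points = []
    for t in thresholds:
        tp = int((pos >= t).sum())
        fp = int((neg >= t).sum())
        table = ConfusionTable(tp, fp, n_pos - tp, n_neg - fp)
        points.append(ROCPoint(t, tp / n_pos, fp / n_neg, table))
    return ROCCurve(tuple(points), n_pos, n_neg)


@dataclass(frozen=True)
class AUROCEstimate:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    se_method: str = "hanley-mcneil"


def _pairwise_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC (ties count half) via midranks, O(n log n)."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _delong_se(pos: np.ndarray, neg: np.ndarray, a: float) -> float:
    """Pairwise structural-component variance (DeLong-style, one curve)."""
    v_pos = np.empty(len(pos))
    v_neg = np.empty(len(neg))
    for i, s in enumerate(pos):
        v_pos[i] = ((s > neg).sum() + 0.5 * (s == neg).sum()) / len(neg)
    for j, s in enumerate(neg):
        v_neg[j] = ((pos > s).sum() + 0.5 * (pos == s).sum()) / len(pos)
    var = (
        np.var(v_pos, ddof=1) / len(pos) if len(pos) > 1 else 0.0
    ) + (np.var(v_neg, ddof=1) / len(neg) if len(neg) > 1 else 0.0)
    return math.sqrt(max(float(var), 0.0))


def auroc(
    scores: dict[str, float],
    truth: dict[str, bool],
    alpha: float = 0.05,
    se_method: str = "hanley-mcneil",
) -> AUROCEstimate:
    """Area under the ROC curve with a Wald interval.

    AUC is the probability a random positive outscores a random negative,
    ties counted half. SE defaults to Hanley-McNeil; "delong" switches to
    the pairwise structural-component variance.
    """
    pos, neg = _split_scores(scores, truth)
    a = _pairwise_auc(pos, neg)
    if se_method == "hanley-mcneil":
        se = _hanley_mcneil_se(a, len(pos), len(neg))
    elif se_method == "delong":
        se = _delong_se(pos, neg, a)
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    z = stats.norm.ppf(1 - alpha / 2)
    return AUROCEstimate(
        auc=a,
        se=se,
        ci_low=max(0.0, a - z * se),
        ci_high=min(1.0, a + z * se),
        alpha=alpha,
        se_method=se_method,
    )


@dataclass(frozen=True)
class CutoffSelection:
    rule: str
    threshold: float | None
    j: float | None = None
    metrics_at_cutoff: dict = field(default_factory=dict)
    constraint_met: bool = True


def _point_metrics(point: ROCPoint, alpha: float) -> dict[str, MetricEstimate]:
    return all_metrics(point.table, alpha)


def select_cutoff_constrained(
    curve: ROCCurve,
    min_ppv: float = 0.90,
    target_sens: float = 0.80,
    alpha: float = 0.05,
) -> CutoffSelection:
    """Researcher rule: among thresholds whose PPV exceeds ``min_ppv``,
    maximize sensitivity (ties to the lowest threshold). When no threshold
    clears the PPV floor, fall back to the max-PPV threshold and flag the
    constraint as unmet. ``target_sens`` is advisory only."""
    qualifying = []
    fallback = []
    for p in curve.points:
        tp, fp = p.table.tp, p.table.fp
        if tp + fp == 0:
            continue  # PPV undefined at the sentinel
        ppv = tp / (tp + fp)
        fallback.append((ppv, -p.threshold, p))
        if ppv > min_ppv:
            qualifying.append((p.tpr, -p.threshold, p))
    if qualifying:
        _, _, best = max(qualifying)
        met = True
    elif fallback:
        _, _, best = max(fallback)
        met = False
    else:  # degenerate: every threshold calls nothing positive
        best = curve.points[0]
        met = False
    return CutoffSelection(
        rule="constrained",
        threshold=best.threshold,
        metrics_at_cutoff=_point_metrics(best, alpha),
        constraint_met=met,
    )


def select_cutoff_youden(curve: ROCCurve, alpha: float = 0.05) -> CutoffSelection:
    """Threshold maximizing J = tpr - fpr; ties to the lowest threshold."""
    best = max(curve.points, key=lambda p: (p.tpr - p.fpr, -p.threshold))
    return CutoffSelection(
        rule="youden",
        threshold=best.threshold,
        j=best.tpr - best.fpr,
        metrics_at_cutoff=_point_metrics(best, alpha),
    )


def select_cutoff_sens_eq_spec(
    curve: ROCCurve, tolerance: float = 0.02, alpha: float = 0.05
) -> CutoffSelection:
    """Threshold minimizing |sensitivity - specificity|.

    Coarse score lattices may have no threshold near the crossing; when the
    smallest gap exceeds ``tolerance`` the selection reports no threshold.
    """
    best = min(curve.points, key=lambda p: (abs(p.tpr - (1 - p.fpr)), p.threshold))
    gap = abs(best.tpr - (1 - best.fpr))
    if gap > tolerance + 1e-9:  # epsilon absorbs float error in 1 - fpr
        return CutoffSelection(rule="sens_eq_spec", threshold=None, j=best.tpr - best.fpr)
    return CutoffSelection(
        rule="sens_eq_spec",
        threshold=best.threshold,
        j=best.tpr - best.fpr,
        metrics_at_cutoff=_point_metrics(best, alpha),
    )


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the sensitivity-driven sample-size calculation."""

    sensitivity: float
    marginal_error: float
    prevalence: float
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.sensitivity < 1:
            raise ValueError("sensitivity must be in (0,1)")
        if self.marginal_error <= 0:
            raise ValueError("marginal_error must be > 0")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0,1]")

    @property
    def z(self) -> float:
        return float(stats.norm.ppf(1 - self.alpha / 2))


def sample_size_sensitivity(spec: SampleSizeSpec) -> int:
    """n = round(z^2 * S(1-S) / (d^2 * prevalence)).

    Rounded to the nearest integer rather than ceiling: only rounding is
    consistent with the published worked value this mirrors.
    """
    s = spec.sensitivity
    n = spec.z**2 * s * (1 - s) / (spec.marginal_error**2 * spec.prevalence)
    return int(round(n))


def prevalence(positives: int, total: int) -> float:
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= positives <= total:
        raise ValueError("require 0 <= positives <= total")
    return positives / total


def merge_adjudications(
    labels_a: dict[str, bool],
    labels_b: dict[str, bool],
    resolutions: dict[str, bool] | None = None,
) -> tuple[dict[str, bool], list[str]]:
    """Merge two independent binary adjudications into a consensus.

    Agreeing records take the common label. Disagreements are returned for
    external resolution; a ``resolutions`` table (id -> label) completes
    them. Remaining unresolved ids are listed and left out of the consensus.
    """
    if set(labels_a) != set(labels_b):
        raise AlignmentError("adjudication tables must cover identical ids")
    resolutions = resolutions or {}
    consensus: dict[str, bool] = {}
    disagreements: list[str] = []
    for rid in labels_a:
        if labels_a[rid] == labels_b[rid]:
            consensus[rid] = labels_a[rid]
        elif rid in resolutions:
            consensus[rid] = resolutions[rid]
        else:
            disagreements.append(rid)
    return consensus, sorted(disagreements)
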