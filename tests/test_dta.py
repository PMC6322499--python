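import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from carematch.dta import (
    AlignmentError,
    ConfusionTable,
    SampleSizeSpec,
    UndefinedMetricError,
    all_metrics,
    auroc,
    build_confusion,
    clopper_pearson,
    merge_adjudications,
    metric,
    prevalence,
    roc_curve,
    sample_size_sensitivity,
    select_cutoff_constrained,
    select_cutoff_sens_eq_spec,
    select_cutoff_youden,
)


class TestBuildConfusion:
    def test_enumeration(self):
        calls = {"a": True, "b": True, "c": False, "d": False}
        truth = {"a": True, "b": False, "c": True, "d": False}
        t = build_confusion(calls, truth)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 1)

    def test_all_correct(self):
        calls = {"a": True, "b": False}
        t = build_confusion(calls, dict(calls))
        assert t.fp == t.fn == 0

    def test_empty_is_error(self):
        with pytest.raises(AlignmentError):
            build_confusion({}, {})

    def test_misalignment_lists_ids(self):
        with pytest.raises(AlignmentError, match="x"):
            build_confusion({"x": True}, {"y": True})

    @given(st.dictionaries(st.text(min_size=1, max_size=4),
                           st.tuples(st.booleans(), st.booleans()),
                           min_size=1, max_size=40))
    def test_conservation(self, data):
        calls = {k: v[0] for k, v in data.items()}
        truth = {k: v[1] for k, v in data.items()}
        assert build_confusion(calls, truth).total == len(data)


class TestMetric:
    def test_sensitivity_point(self):
        t = ConfusionTable(tp=385, fp=9, fn=46, tn=4560)
        assert metric(t, "sensitivity").percent == 89.3

    def test_zero_successes_closed_form(self):
        low, high = clopper_pearson(0, 10)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 10))

    def test_all_successes_boundary(self):
        t = ConfusionTable(tp=5, fp=0, fn=0, tn=5)
        est = metric(t, "sensitivity")
        assert est.point == 1.0 and est.ci_high == 1.0

    def test_undefined_ppv(self):
        t = ConfusionTable(tp=0, fp=0, fn=3, tn=7)
        with pytest.raises(UndefinedMetricError):
            metric(t, "ppv")
        assert "ppv" not in all_metrics(t)

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            metric(ConfusionTable(1, 1, 1, 1), "accuracy")

    @given(st.integers(0, 40), st.integers(0, 40))
    def test_interval_brackets_point(self, x, extra):
        n = x + extra
        if n == 0:
            return
        low, high = clopper_pearson(x, n)
        assert 0 <= low <= x / n <= high <= 1

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (20, 80, 320):
            x = int(0.9 * n)
            low, high = clopper_pearson(x, n)
            widths.append(high - low)
        assert widths[0] > widths[1] > widths[2]

    def test_coverage_quick_simulation(self):
        # exact intervals must cover at >= nominal rate
        rng = np.random.default_rng(42)
        p, n, reps = 0.9, 50, 500
        draws = rng.binomial(n, p, size=reps)
        covered = 0
        for x in draws:
            low, high = clopper_pearson(int(x), n)
            covered += low <= p <= high
        mc_err = math.sqrt(0.95 * 0.05 / reps)
        assert covered / reps >= 0.95 - 3 * mc_err


def brute_force_roc(scores, truth):
    """Oracle: sweep every threshold, count directly."""
    pos = [s for r, s in scores.items() if truth[r]]
    neg = [s for r, s in scores.items() if not truth[r]]
    out = []
    for t in sorted(set(scores.values())) + [max(scores.values()) + 1]:
        tpr = sum(s >= t for s in pos) / len(pos)
        fpr = sum(s >= t for s in neg) / len(neg)
        out.append((t, tpr, fpr))
    return out


def pairwise_auc(scores, truth):
    """Oracle: exhaustive (positive, negative) pair comparison."""
    pos = [s for r, s in scores.items() if truth[r]]
    neg = [s for r, s in scores.items() if not truth[r]]
    total = 0.0
    for sp, sn in itertools.product(pos, neg):
        total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def _random_instance(seed, n_max=30):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    truth = {}
    scores = {}
    while True:
        for i in range(n):
            truth[f"r{i}"] = bool(rng.random() < 0.5)
            scores[f"r{i}"] = float(rng.integers(0, 8))  # coarse -> many ties
        if any(truth.values()) and not all(truth.values()):
            return scores, truth


class TestROC:
    def test_separated(self):
        scores = {"p1": 90.0, "p2": 80.0, "n1": 10.0}
        truth = {"p1": True, "p2": True, "n1": False}
        curve = roc_curve(scores, truth)
        at80 = next(p for p in curve.points if p.threshold == 80.0)
        assert at80.tpr == 1.0 and at80.fpr == 0.0

    def test_all_identical_scores(self):
        scores = {"a": 5.0, "b": 5.0, "c": 5.0}
        truth = {"a": True, "b": False, "c": False}
        curve = roc_curve(scores, truth)
        corners = {(p.fpr, p.tpr) for p in curve.points}
        assert corners == {(1.0, 1.0), (0.0, 0.0)}

    def test_endpoints_present(self):
        scores, truth = _random_instance(0)
        curve = roc_curve(scores, truth)
        corners = {(p.fpr, p.tpr) for p in curve.points}
        assert (1.0, 1.0) in corners and (0.0, 0.0) in corners

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        scores, truth = _random_instance(seed)
        curve = roc_curve(scores, truth)
        assert [(p.threshold, p.tpr, p.fpr) for p in curve.points] == brute_force_roc(scores, truth)

    def test_monotone_in_threshold(self):
        scores, truth = _random_instance(5)
        curve = roc_curve(scores, truth)
        tprs = [p.tpr for p in curve.points]
        fprs = [p.fpr for p in curve.points]
        assert tprs == sorted(tprs, reverse=True)
        assert fprs == sorted(fprs, reverse=True)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve({"a": 1.0, "b": 2.0}, {"a": True, "b": True})


class TestAUROC:
    def test_perfect_separation(self):
        scores = {"p": 90.0, "q": 80.0, "n": 10.0}
        truth = {"p": True, "q": True, "n": False}
        assert auroc(scores, truth).auc == 1.0

    def test_hand_counted_pairs(self):
        scores = {"p1": 13.0, "p2": 25.0, "p3": 0.0, "n1": 0.0, "n2": 0.0, "n3": 13.0}
        truth = {"p1": True, "p2": True, "p3": True, "n1": False, "n2": False, "n3": False}
        assert auroc(scores, truth).auc == pytest.approx(6.5 / 9)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pairwise_oracle(self, seed):
        scores, truth = _random_instance(seed)
        assert auroc(scores, truth).auc == pytest.approx(pairwise_auc(scores, truth))

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_trapezoid_under_roc(self, seed):
        scores, truth = _random_instance(seed)
        curve = roc_curve(scores, truth)
        pts = sorted((p.fpr, p.tpr) for p in curve.points)
        trap = float(np.trapezoid([t for _, t in pts], [f for f, _ in pts]))
        assert auroc(scores, truth).auc == pytest.approx(trap)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_under_monotone_transform(self, seed):
        scores, truth = _random_instance(seed)
        transformed = {k: math.exp(v / 3.0) + v for k, v in scores.items()}
        assert auroc(scores, truth).auc == pytest.approx(auroc(transformed, truth).auc)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(99)
        scores = {f"r{i}": float(rng.normal()) for i in range(4000)}
        truth = {k: bool(rng.random() < 0.5) for k in scores}
        assert abs(auroc(scores, truth).auc - 0.5) < 0.05

    def test_wald_limits_clipped_and_ordered(self):
        scores = {"p": 9.0, "n": 1.0, "q": 8.0, "m": 2.0}
        truth = {"p": True, "q": True, "n": False, "m": False}
        est = auroc(scores, truth)
        assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0

    def test_delong_switch(self):
        scores, truth = _random_instance(3)
        hm = auroc(scores, truth, se_method="hanley-mcneil")
        dl = auroc(scores, truth, se_method="delong")
        assert hm.auc == dl.auc
        assert dl.se >= 0.0


class TestCutoffs:
    def _curve(self, pairs):
        """pairs: list of (score, is_positive)"""
        scores = {f"r{i}": float(s) for i, (s, _) in enumerate(pairs)}
        truth = {f"r{i}": y for i, (_, y) in enumerate(pairs)}
        return roc_curve(scores, truth), scores, truth

    def test_constrained_prefers_sensitivity_over_ppv(self):
        # threshold 10: ppv 1.0, sens 0.5; threshold 5: ppv ~0.91 > 0.9, sens 1.0
        pairs = [(10, True)] * 5 + [(5, True)] * 5 + [(5, False)] * 1 + [(0, False)] * 20
        curve, _, _ = self._curve(pairs)
        sel = select_cutoff_constrained(curve, min_ppv=0.90)
        assert sel.threshold == 5.0 and sel.constraint_met

    def test_constrained_fallback_max_ppv(self):
        pairs = [(10, True), (10, False), (5, True), (5, False), (0, False)]
        curve, _, _ = self._curve(pairs)
        sel = select_cutoff_constrained(curve, min_ppv=0.90)
        assert not sel.constraint_met
        # ppv 0.5 at thresholds 5 and 10 beats 0.4 at 0; ties -> lowest
        assert sel.threshold == 5.0

    def test_single_threshold_curve(self):
        pairs = [(5, True), (5, False)]
        curve, _, _ = self._curve(pairs)
        assert select_cutoff_constrained(curve).threshold == 5.0

    def test_youden_perfect_test(self):
        pairs = [(90, True)] * 3 + [(10, False)] * 3
        curve, _, _ = self._curve(pairs)
        sel = select_cutoff_youden(curve)
        assert sel.j == pytest.approx(1.0) and sel.threshold == 90.0

    def test_youden_useless_test(self):
        pairs = [(5, True), (5, False)]
        curve, _, _ = self._curve(pairs)
        assert select_cutoff_youden(curve).j == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_youden_matches_exhaustive(self, seed):
        scores, truth = _random_instance(seed)
        curve = roc_curve(scores, truth)
        sel = select_cutoff_youden(curve)
        best_j = max(p.tpr - p.fpr for p in curve.points)
        assert sel.j == pytest.approx(best_j)
        candidates = [p.threshold for p in curve.points
                      if p.tpr - p.fpr == pytest.approx(best_j)]
        assert sel.threshold == min(candidates)

    def test_sens_eq_spec_exact_crossing(self):
        # at threshold 5: tpr = 2/3 and spec = 2/3 exactly
        pairs = [(5, True), (5, True), (0, True), (5, False), (0, False), (0, False)]
        curve, _, _ = self._curve(pairs)
        sel = select_cutoff_sens_eq_spec(curve, tolerance=0.0)
        assert sel.threshold == 5.0

    def test_sens_eq_spec_none_on_coarse_lattice(self):
        pairs = [(10, True)] * 9 + [(10, False)] * 1 + [(0, True)] * 1 + [(0, False)] * 2
        curve, _, _ = self._curve(pairs)
        sel = select_cutoff_sens_eq_spec(curve, tolerance=0.05)
        assert sel.threshold is None

    def test_sens_eq_spec_tolerance_one_always_selects(self):
        scores, truth = _random_instance(11)
        curve = roc_curve(scores, truth)
        assert select_cutoff_sens_eq_spec(curve, tolerance=1.0).threshold is not None

    @pytest.mark.parametrize("seed", range(20))
    def test_sens_eq_spec_matches_exhaustive(self, seed):
        scores, truth = _random_instance(seed)
        curve = roc_curve(scores, truth)
        sel = select_cutoff_sens_eq_spec(curve, tolerance=1.0)
        best_gap = min(abs(p.tpr - (1 - p.fpr)) for p in curve.points)
        chosen = next(p for p in curve.points if p.threshold == sel.threshold)
        assert abs(chosen.tpr - (1 - chosen.fpr)) == pytest.approx(best_gap)


class TestSampleSize:
    def test_published_worked_value(self):
        spec = SampleSizeSpec(sensitivity=0.85, marginal_error=0.05, prevalence=0.04)
        assert sample_size_sensitivity(spec) == 4898

    def test_full_prevalence(self):
        spec = SampleSizeSpec(sensitivity=0.85, marginal_error=0.05, prevalence=1.0)
        assert sample_size_sensitivity(spec) == 196

    def test_half_sensitivity_maximal(self):
        sizes = {
            s: sample_size_sensitivity(SampleSizeSpec(s, 0.05, 0.04))
            for s in (0.1, 0.3, 0.5, 0.7, 0.9)
        }
        assert max(sizes, key=sizes.get) == 0.5

    def test_invalid_prevalence(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(sensitivity=0.85, marginal_error=0.05, prevalence=0.0)


class TestPrevalence:
    def test_pooled_study_value(self):
        assert round(100 * prevalence(1455, 20000), 1) == 7.3

    def test_bounds(self):
        assert prevalence(0, 5) == 0.0
        assert prevalence(5, 5) == 1.0

    def test_zero_total(self):
        with pytest.raises(ValueError):
            prevalence(0, 0)


class TestMergeAdjudications:
    def test_full_agreement(self):
        a = {"x": True, "y": False}
        consensus, disagreements = merge_adjudications(a, dict(a))
        assert consensus == a and disagreements == []

    def test_single_conflict_listed(self):
        a = {"x": True, "y": False}
        b = {"x": True, "y": True}
        consensus, disagreements = merge_adjudications(a, b)
        assert consensus == {"x": True} and disagreements == ["y"]

    def test_resolution_table_completes(self):
        a = {"x": True, "y": False}
        b = {"x": True, "y": True}
        consensus, disagreements = merge_adjudications(a, b, resolutions={"y": True})
        assert consensus == {"x": True, "y": True} and disagreements == []

    def test_id_mismatch(self):
        with pytest.raises(AlignmentError):
            merge_adjudications({"x": True}, {"z": True})
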