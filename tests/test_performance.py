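"""ROC construction, AUC, optimal cut-off, 2x2 metrics, group comparison."""

import numpy as np
import pytest

from petln.cohort import ContingencyTable, build_contingency
from petln.performance import (
    auc,
    compare_groups,
    metrics_from_contingency,
    optimal_cutoff,
    roc_curve,
    round_half_up,
)
from petln.simulate import reference_class_distributions


def pairwise_auc(values, labels):
    """O(n^2) concordance oracle: P(malignant > benign) with ties as 1/2."""
    v = np.asarray(values, float)
    lab = np.asarray(labels, bool)
    x, y = v[lab], v[~lab]
    total = 0.0
    for xi in x:
        for yj in y:
            total += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return total / (len(x) * len(y))


def random_cohort(rng, n_max=60):
    n = int(rng.integers(6, n_max + 1))
    labels = rng.random(n) < rng.uniform(0.2, 0.5)
    if labels.all() or not labels.any():
        labels[0] = True
        labels[1] = False
    values = np.round(rng.uniform(0.5, 20.0, n), 2)  # rounding induces ties
    values[labels] += rng.uniform(0.0, 5.0)
    return values, labels


class TestROCCurve:
    def test_perfect_separation_reaches_ideal_corner(self):
        curve = roc_curve([1, 2, 3, 4], [False, False, True, True])
        pts = {(s, p) for _, s, p in curve.operating_points()}
        assert (1.0, 1.0) in pts  # threshold 3: all malignant >= 3, no benign
        assert (1.0, 0.0) in pts and (0.0, 1.0) in pts

    def test_identical_values_only_degenerate_points(self):
        curve = roc_curve([2.0, 2.0, 2.0], [True, False, True])
        assert set(zip(curve.sensitivity, curve.specificity)) == {(1.0, 0.0), (0.0, 1.0)}

    def test_sensitivity_non_increasing_in_threshold(self, rng):
        values, labels = random_cohort(rng)
        curve = roc_curve(values, labels)
        assert np.all(np.diff(curve.sensitivity) <= 0)
        assert np.all(np.diff(curve.specificity) >= 0)

    def test_operating_points_match_brute_force_contingency(self, rng):
        for _ in range(20):
            values, labels = random_cohort(rng)
            curve = roc_curve(values, labels)
            for t, sens, spec in curve.operating_points():
                if not np.isfinite(t):
                    continue
                ct = build_contingency(values, labels, t)
                m = metrics_from_contingency(ct)
                assert sens == pytest.approx(m.sensitivity, abs=1e-12)
                assert spec == pytest.approx(m.specificity, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            roc_curve([1, 2, 3], [True, True, True])


class TestAUC:
    def test_perfect_separation_gives_one(self):
        assert auc([1, 2, 10, 11], [False, False, True, True]).auc == 1.0

    def test_uninformative_constant_values_give_half(self):
        assert auc([3.0] * 8, [True, False] * 4).auc == pytest.approx(0.5)

    def test_trapezoid_equals_pairwise_concordance(self, rng):
        for _ in range(20):
            values, labels = random_cohort(rng, n_max=30)
            est = auc(values, labels)
            assert est.auc == pytest.approx(pairwise_auc(values, labels), abs=1e-12)

    def test_orientation_flip_complements_auc(self, rng):
        values, labels = random_cohort(rng)
        a = auc(values, labels).auc
        b = auc(-values, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_confidence_interval_brackets_estimate(self, rng):
        values, labels = random_cohort(rng)
        for method in ("delong", "hanley-mcneil"):
            est = auc(values, labels, method=method)
            assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0

    def test_delong_agrees_with_independent_implementation(self, rng):
        # cross-check against sklearn's AUC (point estimate only)
        from sklearn.metrics import roc_auc_score
        for _ in range(5):
            values, labels = random_cohort(rng)
            assert auc(values, labels).auc == pytest.approx(
                roc_auc_score(labels, values), abs=1e-12)


class TestOptimalCutoff:
    def test_perfect_separation_gives_zero_distance(self):
        curve = roc_curve([1, 2, 10, 11], [False, False, True, True])
        res = optimal_cutoff(curve)
        assert res.d == 0.0
        assert res.threshold == 10.0

    def test_tie_break_prefers_higher_specificity(self):
        # two thresholds with symmetric (sens, spec): (0.9, 0.8) and (0.8, 0.9)
        values = np.concatenate([
            np.arange(1, 11),       # benign 1..10
            np.arange(2.5, 12.5),   # malignant 2.5..11.5
        ])
        labels = np.array([False] * 10 + [True] * 10)
        curve = roc_curve(values, labels)
        d = np.hypot(1 - curve.sensitivity, 1 - curve.specificity)
        ties = np.isclose(d, d.min())
        res = optimal_cutoff(curve)
        assert res.specificity == pytest.approx(max(curve.specificity[ties]))

    def test_matches_exhaustive_minimization(self, rng):
        for _ in range(20):
            values, labels = random_cohort(rng)
            curve = roc_curve(values, labels)
            res = optimal_cutoff(curve)
            for t in np.unique(values):
                m = metrics_from_contingency(build_contingency(values, labels, t))
                d = np.hypot(1 - m.sensitivity, 1 - m.specificity)
                assert res.d <= d + 1e-12


class TestMetrics:
    def test_reference_suvmax_row(self):
        m = metrics_from_contingency(ContingencyTable(tn=64, fp=8, fn=3, tp=26))
        pct = m.as_percentages()
        assert pct["specificity"] == 88.89
        assert pct["ppv"] == 76.47
        assert pct["npv"] == 95.52
        assert pct["accuracy"] == 89.11
        assert pct["sensitivity"] == 89.66  # 26/29; the printed 89.67 is a misprint

    def test_reference_lung_row(self):
        m = metrics_from_contingency(ContingencyTable(tn=53, fp=19, fn=0, tp=29))
        pct = m.as_percentages()
        assert pct["sensitivity"] == 100.0
        assert pct["npv"] == 100.0
        assert pct["specificity"] == 73.61
        assert pct["ppv"] == 60.42

    def test_two_correct_calls_give_all_hundred(self):
        pct = metrics_from_contingency(ContingencyTable(1, 0, 0, 1)).as_percentages()
        assert all(v == 100.0 for v in pct.values())

    def test_undefined_metric_is_none_not_zero(self):
        m = metrics_from_contingency(ContingencyTable(tn=5, fp=0, fn=2, tp=0))
        assert m.ppv is None  # no positive calls
        assert m.as_percentages()["ppv"] is None
        assert m.accuracy == pytest.approx(5 / 7)

    def test_rounding_is_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(89.655172, 2) == 89.66


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        assert compare_groups([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_separated_groups_highly_significant(self):
        b = np.arange(1.0, 21.0)
        m = np.arange(100.0, 120.0)
        assert compare_groups(b, m) < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])

    def test_calibrated_class_sizes_detect_shift(self):
        # benign/malignant SUVmax at the clinical class sizes (72 vs 29):
        # the shift should be detected in nearly every replicate
        dists = reference_class_distributions()
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            b = dists["benign"]["suvmax"].sample(rng, 72)
            m = dists["malignant"]["suvmax"].sample(rng, 29)
            hits += compare_groups(b, m) < 0.05
        assert hits >= int(0.95 * n_rep)
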