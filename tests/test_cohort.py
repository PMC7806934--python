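"""Cohort statistics: t-tests, ROC against a concordance oracle, quadrant
classification, 2x2 reconstruction and the screening-metric arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphoscreen import (
    CANCER_GROUP,
    NORMAL_GROUP,
    CohortSimParams,
    ConfusionTable,
    CutoffPoint,
    compare_groups,
    confusion_from_rates,
    correlation_r2,
    evaluate_cutoffs,
    generate_cohort,
    quadrant_classify,
    roc_curve,
    screening_metrics,
)


def concordance_auc(scores, labels):
    """Brute-force AUC: P(case score > control score) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_pooled_variance_hand_formula(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        t, p = compare_groups(a, b, equal_var=True)
        # pooled s^2 = 1, se = sqrt(2/3)
        assert t == pytest.approx(-10.0 / math.sqrt(2.0 / 3.0))
        assert p < 1e-3

    def test_simulated_cohort_separates_groups(self):
        cohort = generate_cohort(CohortSimParams(n_cancer=358, n_normal=363, seed=1))
        cancer = cohort.loc[cohort["group"] == "cancer", "avg_intensity"]
        normal = cohort.loc[cohort["group"] == "normal", "avg_intensity"]
        t, p = compare_groups(cancer, normal)
        assert t > 0 and p < 1e-4

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestRocCurve:
    def test_perfect_separation_gives_unit_auc(self):
        _, auc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        _, auc = roc_curve(scores, labels)
        assert abs(auc - 0.5) < 0.03

    def test_six_score_instance_matches_concordance_oracle(self):
        scores = [3.0, 1.0, 2.0, 2.0, 5.0, 4.0]
        labels = [1, 0, 0, 1, 1, 0]
        _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(concordance_auc(scores, labels))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_auc_equals_concordance_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        scores = rng.integers(0, 8, size=n).astype(float)  # ties likely
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            return
        _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(concordance_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [1, 1])


class TestQuadrantClassify:
    CUT_B = CutoffPoint(90.28, 53.34, "B")

    @pytest.mark.parametrize(
        "intensity,pct,expected",
        [
            (200.0, 0.0, "positive"),    # intensity alone suffices
            (0.0, 90.0, "positive"),     # percentage alone suffices
            (0.0, 0.0, "negative"),      # lower-left quadrant
            (90.28, 53.34, "positive"),  # exactly on the cut (inclusive)
            (90.27, 53.33, "negative"),  # just below both
        ],
    )
    def test_quadrant_rule(self, intensity, pct, expected):
        sample = {"avg_intensity": intensity, "pct_positive": pct}
        assert quadrant_classify(sample, self.CUT_B) == expected

    def test_undefined_statistics_rejected(self):
        with pytest.raises(ValueError):
            quadrant_classify(
                {"avg_intensity": float("nan"), "pct_positive": 10.0}, self.CUT_B
            )

    def test_infinite_y_degenerates_to_intensity_rule(self):
        # with the percentage axis switched off, the quadrant rule is the
        # single-axis score >= threshold rule, so its operating point must
        # sit exactly on the ROC curve at that threshold
        rng = np.random.default_rng(3)
        cohort = generate_cohort(CohortSimParams(n_cancer=80, n_normal=80, seed=3))
        cut = CutoffPoint(90.28, float("inf"))
        calls = [
            quadrant_classify(row, cut) == "positive"
            for _, row in cohort.iterrows()
        ]
        manual = (cohort["avg_intensity"] >= 90.28).tolist()
        assert calls == manual
        scores = cohort["avg_intensity"].to_numpy()
        labels = (cohort["group"] == "cancer").astype(int).to_numpy()
        scores_with_thr = np.append(scores, 90.28)
        labels_with_thr = np.append(labels, 0)
        curve, _ = roc_curve(scores_with_thr, labels_with_thr)
        row = curve.loc[np.isclose(curve["threshold"], 90.28)].iloc[0]
        diseased = labels == 1
        sens = np.mean(np.array(calls)[diseased])
        assert row["sensitivity"] == pytest.approx(sens)


class TestConfusionFromRates:
    @pytest.mark.parametrize(
        "sens,spec,nd,nh,expected",
        [
            (1.0, 1.0, 358, 363, (358, 0, 363, 0)),
            (0.8296, 0.8347, 358, 363, (297, 61, 303, 60)),
            (0.3715, 0.9917, 358, 363, (133, 225, 360, 3)),
        ],
    )
    def test_reconstruction_arithmetic(self, sens, spec, nd, nh, expected):
        t = confusion_from_rates(sens, spec, nd, nh)
        assert (t.tp, t.fn, t.tn, t.fp) == expected

    def test_round_half_up(self):
        t = confusion_from_rates(0.5, 0.5, 3, 3)  # 1.5 rounds to 2
        assert (t.tp, t.tn) == (2, 2)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_recovers_rates_within_rounding(self, sens, spec):
        nd, nh = 358, 363
        m = screening_metrics_or_none(confusion_from_rates(sens, spec, nd, nh))
        if m is None:
            return
        assert abs(m.sensitivity - sens) <= 0.5 / nd + 1e-12
        assert abs(m.specificity - spec) <= 0.5 / nh + 1e-12


def screening_metrics_or_none(table):
    try:
        return screening_metrics(table)
    except ValueError:
        return None


class TestScreeningMetrics:
    def test_balanced_cutoff_worked_example(self):
        m = screening_metrics(ConfusionTable(tp=297, fn=61, tn=303, fp=60))
        assert m.odds_ratio == pytest.approx(24.59, abs=0.005)
        assert m.or_ci_95[0] == pytest.approx(16.64, abs=0.005)
        assert m.or_ci_95[1] == pytest.approx(36.34, abs=0.005)
        assert m.accuracy == pytest.approx(0.8322, abs=5e-5)
        assert m.npv == pytest.approx(0.8324, abs=5e-5)
        assert m.ppv == pytest.approx(0.8319, abs=5e-5)

    def test_high_specificity_worked_example(self):
        m = screening_metrics(ConfusionTable(tp=133, fn=225, tn=360, fp=3))
        assert m.npv == pytest.approx(0.6154, abs=5e-5)
        assert m.ppv == pytest.approx(0.9779, abs=5e-5)

    def test_odds_ratio_transpose_invariance(self):
        a = screening_metrics(ConfusionTable(tp=20, fn=5, tn=30, fp=8))
        b = screening_metrics(ConfusionTable(tp=20, fn=8, tn=30, fp=5))
        assert a.odds_ratio == pytest.approx(b.odds_ratio)

    def test_haldane_applied_on_zero_cell(self):
        m = screening_metrics(ConfusionTable(tp=10, fn=0, tn=12, fp=3))
        assert m.haldane_applied
        assert np.isfinite(m.odds_ratio)

    @given(
        st.integers(min_value=1, max_value=200),
        st.integers(min_value=1, max_value=200),
        st.integers(min_value=1, max_value=200),
        st.integers(min_value=1, max_value=200),
    )
    @settings(max_examples=50, deadline=None)
    def test_accuracy_identity_and_ci_contains_or(self, tp, fn, tn, fp):
        m = screening_metrics(ConfusionTable(tp=tp, fn=fn, tn=tn, fp=fp))
        pi = (tp + fn) / (tp + fn + tn + fp)
        assert m.accuracy == pytest.approx(
            m.sensitivity * pi + m.specificity * (1 - pi)
        )
        assert m.or_ci_95[0] <= m.odds_ratio <= m.or_ci_95[1]

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            screening_metrics(ConfusionTable(tp=0, fn=0, tn=10, fp=5))


class TestEvaluateCutoffs:
    def _separated_cohort(self):
        rows = []
        for i in range(20):
            rows.append(("c%d" % i, "cancer", 200.0, 90.0))
            rows.append(("n%d" % i, "normal", 10.0, 5.0))
        return pd.DataFrame(
            rows, columns=["sample_id", "group", "avg_intensity", "pct_positive"]
        )

    def test_perfect_separation_all_cuts(self):
        metrics = evaluate_cutoffs(self._separated_cohort())
        for m in metrics.values():
            assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_duplicating_samples_preserves_rates(self):
        cohort = generate_cohort(CohortSimParams(n_cancer=60, n_normal=60, seed=4))
        once = evaluate_cutoffs(cohort)
        twice = evaluate_cutoffs(pd.concat([cohort, cohort], ignore_index=True))
        for name in once:
            assert once[name].sensitivity == pytest.approx(twice[name].sensitivity)
            assert once[name].specificity == pytest.approx(twice[name].specificity)

    def test_replicate_breakdown(self):
        cohort = generate_cohort(
            CohortSimParams(n_cancer=200, n_normal=200, n_replicate_sets=4, seed=5)
        )
        overall, per_rep = evaluate_cutoffs(cohort, by_replicate=True)
        assert set(per_rep) == set(overall)
        for rep_metrics in per_rep.values():
            assert len(rep_metrics) >= 3  # nearly all strata have both groups

    def test_missing_group_rejected(self):
        cohort = self._separated_cohort()
        with pytest.raises(ValueError):
            evaluate_cutoffs(cohort[cohort["group"] == "cancer"])


class TestCorrelationR2:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        assert correlation_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(6)
        assert correlation_r2(rng.normal(size=5000), rng.normal(size=5000)) < 0.01

    def test_five_point_hand_dataset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # cov(x,y) = 2.0, var(x) = 2.0, var(y) = 2.96 (denominator n)
        assert correlation_r2(x, y) == pytest.approx(2.0**2 / (2.0 * 2.96))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
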