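"""ROC construction, AUC standard errors and contrasts, t-tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from nerveblock.stats import (
    compare_auc,
    roc_from_scores,
    t_test_from_raw,
    t_test_from_summary,
)


def pairwise_auc(pos, neg):
    """Exhaustive concordance count with half-credit for ties."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _scores(pos, neg):
    return [(s, "pos") for s in pos] + [(s, "neg") for s in neg]


class TestROC:
    def test_interleaved_example(self):
        r = roc_from_scores(_scores([3, 5, 7], [2, 4, 6]), "pos")
        assert r.auc == pytest.approx(6 / 9)
        assert r.n_pos == r.n_neg == 3

    def test_perfect_separation(self):
        r = roc_from_scores(_scores([10, 11, 12], [1, 2, 3]), "pos")
        assert r.auc == 1.0 and r.se == 0.0

    def test_identical_multisets(self):
        r = roc_from_scores(_scores([1, 2, 3], [1, 2, 3]), "pos")
        assert r.auc == pytest.approx(0.5)

    def test_curve_anchored_and_monotone(self):
        r = roc_from_scores(_scores([3, 5, 7, 7], [2, 4, 6]), "pos")
        assert r.points[0] == (0.0, 0.0) and r.points[-1] == (1.0, 1.0)
        fpr = [p[0] for p in r.points]
        tpr = [p[1] for p in r.points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate ROC"):
            roc_from_scores([(1.0, "pos"), (2.0, "pos")], "pos")

    @given(
        pos=st.lists(st.integers(0, 8), min_size=1, max_size=6),
        neg=st.lists(st.integers(0, 8), min_size=1, max_size=6),
    )
    def test_trapezoid_equals_concordance_count(self, pos, neg):
        r = roc_from_scores(_scores(pos, neg), "pos")
        assert r.auc == pytest.approx(pairwise_auc(pos, neg), abs=1e-12)

    @given(
        pos=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8),
        neg=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=8),
    )
    def test_label_swap_complements_auc(self, pos, neg):
        scores = _scores(pos, neg)
        a = roc_from_scores(scores, "pos").auc
        b = roc_from_scores(scores, "neg").auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_hanley_mcneil_se_value(self):
        # closed form at AUC=0.75, 10 vs 10: Q1=0.6, Q2=0.642857...
        r = roc_from_scores(_scores(list(range(6, 16)), list(range(1, 11))), "pos")
        a = r.auc
        q1, q2 = a / (2 - a), 2 * a**2 / (1 + a)
        expected = math.sqrt((a * (1 - a) + 9 * (q1 - a**2) + 9 * (q2 - a**2)) / 100)
        assert r.se == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_se_close_to_hanley(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(60, 15, 30)
        neg = rng.normal(40, 15, 30)
        h = roc_from_scores(_scores(pos, neg), "pos")
        b = roc_from_scores(_scores(pos, neg), "pos", se_method="bootstrap", rng=1)
        assert b.auc == h.auc
        assert b.se == pytest.approx(h.se, rel=0.5)  # same order of magnitude


class TestCompareAUC:
    def test_equal_areas(self):
        r = roc_from_scores(_scores([3, 5, 7], [2, 4, 6]), "pos")
        c = compare_auc(r, r)
        assert c.chi2 == 0.0 and c.p_value == 1.0

    def test_hand_computed_contrast(self):
        r1 = roc_from_scores(_scores([3, 5, 7], [2, 4, 6]), "pos")
        r2 = roc_from_scores(_scores([10, 11], [1, 2]), "pos")
        c = compare_auc(
            type(r1)(r1.points, r1.thresholds, 0.9, 0.05, 3, 3, "pos"),
            type(r2)(r2.points, r2.thresholds, 0.7, 0.05, 2, 2, "pos"),
        )
        assert c.chi2 == pytest.approx(8.0, abs=1e-10)
        assert c.p_value == pytest.approx(float(sps.chi2.sf(8.0, 1)), rel=1e-10)
        assert c.df == 1

    def test_symmetric_in_arguments(self):
        r1 = roc_from_scores(_scores([3, 5, 7], [2, 4, 6]), "pos")
        r2 = roc_from_scores(_scores([4, 9, 9], [1, 4, 6]), "pos")
        a, b = compare_auc(r1, r2), compare_auc(r2, r1)
        assert a.chi2 == b.chi2 and a.p_value == b.p_value

    def test_zero_se_unequal_areas_warns(self):
        r1 = roc_from_scores(_scores([10, 11], [1, 2]), "pos")  # AUC 1, SE 0
        r2 = roc_from_scores(_scores([1, 2], [10, 11]), "pos")  # AUC 0, SE 0
        with pytest.warns(UserWarning, match="machine floor"):
            c = compare_auc(r1, r2)
        assert 0 < c.p_value <= 5e-324


class TestTTests:
    def test_neuropathy_baseline_contrast(self):
        res = t_test_from_summary(11.9, 3.4, 12, 6.4, 2.8, 12)
        assert res.t == pytest.approx(4.326, abs=5e-3)
        assert res.df == 22
        assert res.p_value == pytest.approx(2.7e-4, rel=0.05)

    def test_tail_flick_contrast_notable_tier(self):
        res = t_test_from_summary(2.2, 0.4, 12, 1.9, 0.4, 12)
        assert res.t == pytest.approx(1.837, abs=5e-3)
        assert 0.05 < res.p_value < 0.1

    def test_closed_form_oracle(self):
        m1, sd1, n1, m2, sd2, n2 = 2.2, 0.4, 12, 1.9, 0.4, 12
        sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
        t = (m1 - m2) / (sp * math.sqrt(1 / n1 + 1 / n2))
        p = 2 * float(sps.t.sf(abs(t), n1 + n2 - 2))
        res = t_test_from_summary(m1, sd1, n1, m2, sd2, n2)
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_equal_means(self):
        res = t_test_from_summary(5.0, 1.0, 8, 5.0, 2.0, 8)
        assert res.t == 0.0 and res.p_value == 1.0

    def test_degenerate_zero_variance(self):
        assert t_test_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5).p_value == 1.0
        with pytest.warns(UserWarning, match="machine floor"):
            res = t_test_from_summary(3.0, 0.0, 5, 2.0, 0.0, 5)
        assert res.p_value <= 5e-324 and math.isinf(res.t)

    def test_pooled_equals_welch_for_balanced_equal_spread(self):
        a = t_test_from_summary(4.0, 1.2, 10, 3.0, 1.2, 10, variant="pooled")
        b = t_test_from_summary(4.0, 1.2, 10, 3.0, 1.2, 10, variant="welch")
        assert a.t == pytest.approx(b.t, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
        assert a.df == b.df

    @given(
        a=st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=10),
        b=st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=10),
    )
    def test_raw_path_consistent_with_summary_path(self, a, b):
        raw = t_test_from_raw(a, b)
        aa, bb = np.asarray(a), np.asarray(b)
        summ = t_test_from_summary(
            aa.mean(), aa.std(ddof=1), aa.size, bb.mean(), bb.std(ddof=1), bb.size
        )
        assert raw.t == pytest.approx(summ.t, abs=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)

    def test_identical_samples(self):
        res = t_test_from_raw([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p_value == 1.0

    def test_raw_against_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(0.4, 1.3, 12)
        res = t_test_from_raw(a, b, variant="welch")
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(float(ref.statistic), rel=1e-12)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)
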