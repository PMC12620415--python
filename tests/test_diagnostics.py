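import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pulmshear.diagnostics import (
    compare_groups,
    confusion_metrics,
    dunn_test,
    kruskal_wallis,
    roc,
    spearman,
    youden_cutoff,
)

WORKED_GROUPS = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]


class TestKruskalWallis:
    def test_worked_example(self):
        h, p = kruskal_wallis(WORKED_GROUPS)
        assert h == pytest.approx(32 / 7, rel=1e-12)

    def test_identical_groups_degenerate(self):
        groups = [np.full(4, 2.0)] * 3
        assert kruskal_wallis(groups) == (0.0, 1.0)

    def test_permutation_invariance(self):
        h1, _ = kruskal_wallis(WORKED_GROUPS)
        h2, _ = kruskal_wallis(WORKED_GROUPS[::-1])
        assert h1 == pytest.approx(h2)

    def test_agrees_with_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            groups = [rng.integers(0, 8, rng.integers(3, 15)).astype(float)
                      for _ in range(3)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            h, p = kruskal_wallis(groups)
            ref = stats.kruskal(*groups)
            assert h == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.lists(st.floats(-100, 100), min_size=3, max_size=10),
                    min_size=2, max_size=4))
    def test_monotone_transform_invariance(self, groups):
        groups = [np.array(g) for g in groups]
        h1, _ = kruskal_wallis(groups)
        # x -> 8x is strictly monotone and exact in floats (no tie changes)
        h2, _ = kruskal_wallis([g * 8.0 for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0]), np.array([])])


class TestDunn:
    def test_worked_example(self):
        res = dunn_test(WORKED_GROUPS)
        first_last = next(r for r in res if r.pair == (0, 2))
        assert abs(first_last.z) == pytest.approx(4 / np.sqrt(3.5), rel=1e-12)
        assert first_last.p_raw == pytest.approx(0.0325, abs=2e-4)
        assert first_last.p_adjusted == pytest.approx(0.0975, abs=5e-4)

    def test_identical_groups(self):
        res = dunn_test([np.full(4, 1.0)] * 3)
        for r in res:
            assert r.z == 0.0
            assert r.p_adjusted == 1.0

    def test_antisymmetry_under_group_swap(self):
        res_fwd = dunn_test(WORKED_GROUPS)
        res_rev = dunn_test([WORKED_GROUPS[2], WORKED_GROUPS[1], WORKED_GROUPS[0]])
        z_fwd = next(r.z for r in res_fwd if r.pair == (0, 2))
        z_rev = next(r.z for r in res_rev if r.pair == (0, 2))
        assert z_fwd == pytest.approx(-z_rev)

    def test_bonferroni_cap(self):
        res = dunn_test([np.array([1.0, 2.0, 1.5]), np.array([1.2, 1.8, 1.4]),
                         np.array([1.1, 1.9, 1.6])])
        for r in res:
            assert 0.0 <= r.p_adjusted <= 1.0
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))


class TestSpearman:
    def test_monotone_increasing(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman(x, x**3) == pytest.approx(1.0)

    def test_hand_example(self):
        assert spearman(np.array([1.0, 2, 3]), np.array([2.0, 1, 3])) == pytest.approx(0.5)

    def test_sign_flip(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert spearman(x, -y) == pytest.approx(-spearman(x, y))

    def test_rank_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=25), rng.normal(size=25)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        assert spearman(x, y) == pytest.approx(spearman(rx, ry))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))


def brute_force_auc(scores, labels, orientation="lower"):
    """Enumerate every (positive, negative) pair; ties count one half."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if (p < q if orientation == "lower" else p > q):
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc(np.array([1.0, 2, 3, 4]), np.array([True, True, False, False]))
        assert r.AUC == 1.0
        assert r.J_max == pytest.approx(1.0)

    def test_interleaved_auc(self):
        r = roc(np.array([1.0, 2, 3, 4]), np.array([True, False, True, False]))
        assert r.AUC == pytest.approx(0.75)

    def test_all_tied_is_chance(self):
        r = roc(np.ones(10), np.array([True] * 5 + [False] * 5))
        assert r.AUC == pytest.approx(0.5)
        assert r.J_max == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc(np.arange(4.0), np.array([True] * 4))

    def test_curve_monotonicity(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        r = roc(scores, labels)
        order = np.argsort(r.thresholds)
        assert np.all(np.diff(r.sensitivity[order]) >= 0)
        assert np.all(np.diff(r.specificity[order]) <= 0)

    def test_auc_equals_trapezoid_under_curve(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.normal(size=40).round(1)  # force ties
            labels = rng.random(40) < 0.4
            if labels.all() or not labels.any():
                continue
            r = roc(scores, labels)
            fpr = 1 - r.specificity
            order = np.argsort(fpr, kind="stable")
            area = np.trapezoid(r.sensitivity[order], fpr[order])
            assert r.AUC == pytest.approx(area, abs=1e-12)

    def test_auc_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = rng.integers(6, 50)
            scores = rng.normal(size=n).round(1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            r = roc(scores, labels)
            assert r.AUC == brute_force_auc(scores, labels)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.6
        r = roc(scores, labels, orientation="lower")
        # lower-is-positive equals sklearn on the negated score
        assert r.AUC == pytest.approx(roc_auc_score(labels, -scores), abs=1e-12)


class TestYouden:
    def test_perfect(self):
        r = roc(np.array([1.0, 2, 3, 4]), np.array([True, True, False, False]))
        cutoff, j = youden_cutoff(r)
        assert j == pytest.approx(1.0)
        assert 2.0 < cutoff < 3.0

    def test_all_tied_zero(self):
        r = roc(np.ones(8), np.array([True] * 4 + [False] * 4))
        _, j = youden_cutoff(r)
        assert j == pytest.approx(0.0)

    def test_interleaved_tie_break_toward_specificity(self):
        r = roc(np.array([1.0, 2, 3, 4]), np.array([True, False, True, False]))
        cutoff, j = youden_cutoff(r)
        assert j == pytest.approx(0.5)
        assert 1.0 < cutoff < 2.0  # the high-specificity candidate


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        scores = np.array([1.0, 2, 30, 40])
        labels = np.array([True, True, False, False])
        conf, m = confusion_metrics(scores, labels, 10.0)
        assert conf == {"TP": 2, "FP": 0, "TN": 2, "FN": 0}
        for key in ("sensitivity", "specificity", "PPV", "NPV"):
            assert m[key].value == 1.0

    def test_threshold_below_all_scores(self):
        scores = np.array([5.0, 6, 7, 8])
        labels = np.array([True, False, True, False])
        conf, m = confusion_metrics(scores, labels, 1.0)
        assert m["sensitivity"].value == 0.0
        assert m["specificity"].value == 1.0
        assert np.isnan(m["PPV"].value)
        assert m["PPV"].ci_low is None

    def test_published_confusion_table(self):
        """TP=42, FN=18, TN=30, FP=0 reproduces sens 0.70, spec 1.00,
        PPV 1.00, and the derived NPV 0.625."""
        scores = np.concatenate([np.full(42, 20.0), np.full(18, 30.0),
                                 np.full(30, 40.0)])
        labels = np.concatenate([np.ones(60, bool), np.zeros(30, bool)])
        conf, m = confusion_metrics(scores, labels, 27.0)
        assert conf == {"TP": 42, "FP": 0, "TN": 30, "FN": 18}
        assert m["sensitivity"].value == pytest.approx(0.70)
        assert m["specificity"].value == pytest.approx(1.00)
        assert m["PPV"].value == pytest.approx(1.00)
        assert m["NPV"].value == pytest.approx(0.625)

    def test_wilson_interval_hand_formula(self):
        _, m = confusion_metrics(
            np.array([1.0, 2, 3, 10, 11, 12]),
            np.array([True, True, True, False, False, False]),
            5.0,
        )
        # Wilson for 3/3 successes
        z = stats.norm.ppf(0.975)
        n, p = 3, 1.0
        center = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        assert m["sensitivity"].ci_low == pytest.approx(center - half, rel=1e-9)
        assert m["sensitivity"].ci_high == pytest.approx(center + half, rel=1e-9)


class TestCompareGroups:
    def test_bundles_global_and_pairwise(self):
        res = compare_groups(WORKED_GROUPS)
        assert res.H == pytest.approx(32 / 7)
        assert len(res.pairwise) == 3
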