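"""ROC/AUC, operating thresholds, exact CIs and group comparisons."""

import numpy as np
import pytest
from scipy import stats

from vocptb.evaluate import (
    auc,
    auc_ci_bootstrap,
    choose_threshold,
    confusion_stats,
    evaluate_probabilities,
    group_pvalue,
    roc_curve,
)


def brute_force_auc(probs, labels):
    """Concordant-pair counting oracle, quadratic and explicit."""
    probs, labels = np.asarray(probs), np.asarray(labels)
    pos, neg = probs[labels == 1], probs[labels == 0]
    score = 0.0
    for p in pos:
        for n in neg:
            score += 1.0 if p > n else (0.5 if p == n else 0.0)
    return score / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_passes_through_corner(self):
        pts = roc_curve([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert (0.0, 1.0) in pts
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_constant_probabilities_give_diagonal(self):
        assert roc_curve([0.5] * 6, [1, 0, 1, 0, 1, 0]) == [(0.0, 0.0), (1.0, 1.0)]

    def test_anti_separation_passes_through_bottom_corner(self):
        assert (1.0, 0.0) in roc_curve([0.9, 0.8, 0.4, 0.3], [0, 0, 1, 1])

    def test_monotone_in_both_coordinates(self, rng):
        probs, labels = rng.random(30), rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        pts = np.array(roc_curve(probs, labels))
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()


class TestAUC:
    def test_perfect_and_half(self):
        assert auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])[0] == 1.0
        assert auc([0.9, 0.4, 0.35, 0.8], [1, 0, 1, 0])[0] == 0.5  # 2 of 4 pairs concordant

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 21))
            probs = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            a, _ = auc(probs, labels)
            assert a == pytest.approx(brute_force_auc(probs, labels), abs=1e-12)

    def test_equals_trapezoid_of_roc(self, rng):
        for _ in range(10):
            probs = np.round(rng.random(25), 1)
            labels = rng.integers(0, 2, 25)
            labels[:2] = [0, 1]
            pts = np.array(roc_curve(probs, labels))
            assert auc(probs, labels)[0] == pytest.approx(
                np.trapezoid(pts[:, 1], pts[:, 0]), abs=1e-12
            )

    def test_label_flip_symmetry(self, rng):
        probs = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert auc(probs, labels)[0] + auc(probs, 1 - labels)[0] == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        probs = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        squashed = 1 / (1 + np.exp(-7 * probs))
        assert auc(probs, labels)[0] == auc(squashed, labels)[0]
        assert roc_curve(probs, labels) == roc_curve(squashed, labels)
        assert group_pvalue(probs, labels) == group_pvalue(squashed, labels)

    def test_null_labels_concentrate_near_half(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            probs = rng.random(200)
            labels = rng.permutation([0, 1] * 100)
            a, _ = auc(probs, labels)
            hits += 0.4 <= a <= 0.6
        assert hits >= 95

    def test_delong_ci_brackets_point_and_agrees_with_bootstrap(self, rng):
        probs = np.concatenate([rng.normal(0.6, 0.15, 60), rng.normal(0.4, 0.15, 60)])
        labels = np.array([1] * 60 + [0] * 60)
        a, (lo, hi) = auc(probs, labels)
        assert 0 <= lo <= a <= hi <= 1
        blo, bhi = auc_ci_bootstrap(probs, labels, n_boot=500, seed=1)
        assert lo == pytest.approx(blo, abs=0.05) and hi == pytest.approx(bhi, abs=0.05)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            auc([0.2, 0.4], [1, 1])


class TestThreshold:
    def test_perfect_separation_reaches_j_one(self):
        t = choose_threshold([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert 0.4 < t <= 0.8
        c = confusion_stats([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0], t)
        assert c["sensitivity"] + c["specificity"] - 1 == pytest.approx(1.0)

    def test_enumerated_cutpoints_example(self):
        t = choose_threshold([0.9, 0.6, 0.4, 0.1], [1, 1, 0, 0])
        assert 0.4 < t <= 0.6

    def test_identical_probabilities_degenerate(self):
        assert choose_threshold([0.5] * 4, [1, 0, 1, 0]) == 0.5

    def test_ties_resolved_toward_higher_specificity(self):
        # J = 0.5 at t=0.8 (sens .5, spec 1) and at t=0.3 (sens 1, spec .5)
        t = choose_threshold([0.8, 0.3, 0.3, 0.1], [1, 1, 0, 0])
        assert t == 0.8


def clopper_pearson_oracle(k, n, alpha=0.05, grid=200001):
    """CI by direct summation of binomial tails over a probability grid."""
    ps = np.linspace(0, 1, grid)
    lo = 0.0 if k == 0 else ps[stats.binom.sf(k - 1, n, ps) >= alpha / 2].min()
    hi = 1.0 if k == n else ps[stats.binom.cdf(k, n, ps) >= alpha / 2].max()
    return lo, hi


class TestConfusion:
    def test_rate_arithmetic(self):
        probs = [0.9] * 9 + [0.9] * 1 + [0.1] * 9 + [0.1] * 3  # TP FP TN FN
        labels = [1] * 9 + [0] * 1 + [0] * 9 + [1] * 3
        c = confusion_stats(probs, labels, 0.5)
        assert (c["tp"], c["fp"], c["tn"], c["fn"]) == (9, 1, 9, 3)
        assert c["sensitivity"] == 0.75 and c["specificity"] == 0.9

    def test_all_positive_predictions_flag_undefined_npv(self):
        with pytest.warns(RuntimeWarning):
            c = confusion_stats([0.9, 0.8, 0.7], [1, 1, 0], 0.0)
        assert c["specificity"] == 0.0
        assert np.isnan(c["npv"])

    @pytest.mark.parametrize("k,n", [(13, 22), (0, 10), (10, 10), (250, 1000)])
    def test_clopper_pearson_matches_tail_summation(self, k, n):
        probs = [0.9] * k + [0.1] * (n - k) + [0.1]
        labels = [1] * n + [0]
        c = confusion_stats(probs, labels, 0.5)
        assert c["sensitivity"] == pytest.approx(k / n)
        lo, hi = clopper_pearson_oracle(k, n)
        assert c["sensitivity_ci"][0] == pytest.approx(lo, abs=1e-4)
        assert c["sensitivity_ci"][1] == pytest.approx(hi, abs=1e-4)

    def test_ci_contains_rate_and_shrinks_with_n(self):
        widths = []
        for n in (10, 100, 1000):
            k = int(0.6 * n)
            c = confusion_stats([0.9] * k + [0.1] * (n - k) + [0.1], [1] * n + [0], 0.5)
            lo, hi = c["sensitivity_ci"]
            assert lo <= c["sensitivity"] <= hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_stats([], [], 0.5)


class TestGroupPvalue:
    def test_complete_separation_exact(self):
        assert group_pvalue([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], [0, 0, 0, 1, 1, 1]) == pytest.approx(0.1)

    def test_identical_constants_give_one(self):
        assert group_pvalue([0.4] * 6, [0, 0, 0, 1, 1, 1]) == 1.0

    def test_null_pvalues_roughly_uniform(self):
        ps = []
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            probs = rng.random(60)
            labels = np.array([0] * 30 + [1] * 30)
            ps.append(group_pvalue(probs, labels))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_full_report_is_internally_consistent(rng):
    probs = np.concatenate([rng.normal(0.7, 0.15, 40), rng.normal(0.35, 0.15, 40)]).clip(0, 1)
    labels = np.array([1] * 40 + [0] * 40)
    rep = evaluate_probabilities(probs, labels)
    assert rep.sensitivity == rep.tp / (rep.tp + rep.fn)
    assert rep.specificity == rep.tn / (rep.tn + rep.fp)
    assert rep.ppv == rep.tp / (rep.tp + rep.fp)
    assert rep.npv == rep.tn / (rep.tn + rep.fn)
    assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
    assert rep.group_p < 0.01
    fixed = evaluate_probabilities(probs, labels, threshold=0.5)
    assert fixed.threshold == 0.5
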