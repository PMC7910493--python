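import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dhikit import evaluation as ev


def brute_force_auc(labels, scores):
    """Pair counting over all positive-negative pairs, ties count ½."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        truth = np.array([0, 1, 2, 0, 1, 2])
        cm = ev.confusion(truth, truth)
        assert cm.accuracy == 1.0
        assert np.all(np.diag(cm.counts) == 2)

    def test_hand_counted_example(self):
        cm = ev.confusion([0, 0, 1], [0, 1, 1])
        assert cm.accuracy == pytest.approx(2 / 3)
        np.testing.assert_allclose(cm.true_positive_rates, [0.5, 1.0])

    def test_single_class_truth(self):
        cm = ev.confusion([1, 1, 1], [1, 0, 1], classes=(0, 1))
        assert cm.accuracy == pytest.approx(cm.true_positive_rates[1])

    def test_micro_averaged_tprs_reproduce_accuracy(self, rng):
        truth = rng.integers(0, 4, 300)
        pred = rng.integers(0, 4, 300)
        cm = ev.confusion(truth, pred)
        weights = cm.counts.sum(axis=1)
        micro = np.nansum(cm.true_positive_rates * weights) / weights.sum()
        assert micro == pytest.approx(cm.accuracy)

    def test_row_sums_invariant_under_label_permutation(self, rng):
        truth = rng.integers(0, 3, 100)
        pred = rng.integers(0, 3, 100)
        cm = ev.confusion(truth, pred, classes=(0, 1, 2))
        perm = np.array([2, 0, 1])
        cm_p = ev.confusion(perm[truth], perm[pred], classes=(0, 1, 2))
        assert sorted(cm.counts.sum(axis=1)) == sorted(cm_p.counts.sum(axis=1))
        assert cm_p.accuracy == cm.accuracy

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion([], [])


class TestRocAuc:
    def test_worked_example(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.8, 0.35, 0.4, 0.1])
        cs = ev.roc_ovr(scores, labels, positive_class=1)
        assert cs.auc == pytest.approx(0.75)

    def test_perfect_and_random_limits(self):
        labels = np.array([1, 1, 0, 0])
        assert ev.binary_auc(labels, np.array([0.9, 0.8, 0.2, 0.1])) == 1.0
        assert ev.binary_auc(labels, np.full(4, 0.5)) == 0.5

    def test_roc_endpoints(self, rng):
        labels = rng.integers(0, 2, 50)
        scores = rng.uniform(size=50)
        cs = ev.roc_ovr(scores, labels, positive_class=1)
        assert (cs.fpr[0], cs.tpr[0]) == (0.0, 0.0)
        assert (cs.fpr[-1], cs.tpr[-1]) == (1.0, 1.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 50), st.integers(1, 4))
    def test_trapezoid_equals_pair_counting(self, seed, n, dups):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        # duplicate scores force tie handling
        scores = rng.integers(0, dups * n // 2 + 1, n) / (dups * n // 2 + 1)
        assert ev.binary_auc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.binary_auc(np.ones(5), np.arange(5))


class TestYouden:
    def test_perfect_separation(self):
        labels = np.array([1, 1, 0, 0])
        cs = ev.roc_ovr(np.array([0.9, 0.8, 0.2, 0.1]), labels, 1)
        pt = ev.youden_point(cs)
        assert pt["sensitivity"] == 1.0 and pt["specificity"] == 1.0
        assert pt["j"] == 1.0

    def test_tie_broken_toward_specificity(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.2])
        pt = ev.youden_point(ev.roc_ovr(scores, labels, 1))
        assert pt["j"] == pytest.approx(0.5)
        assert pt["sensitivity"] == pytest.approx(0.5)
        assert pt["specificity"] == pytest.approx(1.0)

    def test_all_tied_scores(self):
        labels = np.array([1, 0, 1, 0])
        pt = ev.youden_point(ev.roc_ovr(np.full(4, 0.3), labels, 1))
        assert pt["j"] == pytest.approx(0.0)


class TestPrecisionRecall:
    def test_f1_formula(self):
        truth = np.array([1, 1, 0, 0])
        pred = np.array([1, 0, 1, 0])  # precision 0.5, recall 0.5
        cs = ev.pr_ovr(np.array([0.9, 0.4, 0.8, 0.1]), truth, 1,
                       predicted_labels=pred)
        assert cs.f1 == pytest.approx(0.5)
        truth2 = np.array([1, 1, 0, 0])
        pred2 = np.array([1, 1, 1, 1])  # precision 0.5, recall 1.0
        cs2 = ev.pr_ovr(np.array([0.9, 0.8, 0.7, 0.6]), truth2, 1,
                        predicted_labels=pred2)
        assert cs2.f1 == pytest.approx(2 / 3)

    def test_average_precision_worked_example(self):
        labels = np.array([1, 0, 1, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.1])
        cs = ev.pr_ovr(scores, labels, 1)
        assert cs.pr_auc == pytest.approx(0.5 * (1 + 2 / 3), abs=1e-9)

    def test_perfect_ranking(self):
        labels = np.array([1, 1, 0, 0])
        cs = ev.pr_ovr(np.array([0.9, 0.8, 0.2, 0.1]), labels, 1)
        assert cs.pr_auc == pytest.approx(1.0)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            ev.pr_ovr(np.arange(4), np.zeros(4), 1)


class TestBootstrap:
    def test_constant_metric(self):
        ci = ev.bootstrap_ci(lambda l, s: 0.7, np.ones(20), np.ones(20),
                             n_reps=100, seed=0)
        assert ci.lower == ci.upper == pytest.approx(0.7)

    def test_deterministic_per_seed(self, rng):
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=100)
        a = ev.bootstrap_ci(ev.binary_auc, labels, scores, n_reps=500, seed=4)
        b = ev.bootstrap_ci(ev.binary_auc, labels, scores, n_reps=500, seed=4)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_vectorized_path_matches_generic(self, rng):
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=60)
        fast = ev.bootstrap_ci(ev.binary_auc, labels, scores, n_reps=400, seed=7)

        def slow_auc(l, s):
            return ev.binary_auc(l, s)

        slow = ev.bootstrap_ci(slow_auc, labels, scores, n_reps=400, seed=7)
        assert fast.lower == pytest.approx(slow.lower, abs=1e-12)
        assert fast.upper == pytest.approx(slow.upper, abs=1e-12)

    def test_ci_width_shrinks_with_n(self, rng):
        def width(n):
            labels = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
            scores = np.r_[rng.normal(1.5, 1, n // 2), rng.normal(0, 1, n // 2)]
            ci = ev.bootstrap_ci(ev.binary_auc, labels, scores,
                                 n_reps=2000, seed=1)
            return ci.upper - ci.lower
        assert width(800) < width(50)


class TestMannWhitney:
    def test_complete_separation(self):
        out = ev.mann_whitney([1, 2, 3], [4, 5, 6])
        assert out["U"] == 0.0

    def test_identical_groups(self):
        out = ev.mann_whitney([1, 2, 3], [1, 2, 3])
        assert out["p"] == pytest.approx(1.0, abs=0.05)

    def test_exact_small_sample(self):
        # enumeration over all C(4,2) assignments gives p = 2/3
        out = ev.mann_whitney([1, 3], [2, 4])
        assert out["U"] == 1.0
        assert out["p"] == pytest.approx(2 / 3, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ev.mann_whitney([], [1.0])


class TestGroupStats:
    def make_table(self, means, n=400, sd=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cls, m in means.items():
            rows.append(pd.DataFrame({
                "metric": rng.normal(m, sd, n), "histology_class": cls}))
        return pd.concat(rows, ignore_index=True)

    def test_percent_difference_rounding(self):
        assert ev.percent_difference(0.43, 0.52) == -17.0
        assert ev.percent_difference(0.35, 0.22) == 59.0
        assert ev.percent_difference(0.5, 0.5) == 0.0

    def test_group_means_and_differences(self):
        table = self.make_table({0: 0.43, 1: 0.52})
        out = ev.group_stats(table, "metric", [0, 1])
        assert out["means"][0] == pytest.approx(0.43, abs=0.01)
        assert out["percent_differences"][(0, 1)] == -17.0

    def test_population_sd_convention(self):
        table = pd.DataFrame({"metric": [1.0, 2.0, 3.0],
                              "histology_class": 0})
        out = ev.group_stats(table, "metric", [0], ddof=0)
        assert out["sds"][0] == pytest.approx(np.sqrt(2 / 3))

    def test_missing_class_rejected(self):
        table = self.make_table({0: 0.4})
        with pytest.raises(ValueError):
            ev.group_stats(table, "metric", [0, 3])
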