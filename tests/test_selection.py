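import numpy as np
import pytest

from conftest import simulate_slice
from toplines import selection as sel
from toplines.evaluation import CVPlan, MCMCSettings, evaluate_fold, make_folds


@pytest.fixture()
def top_rule():
    return sel.quantile_threshold(np.arange(1.0, 11.0), tau=0.8)


class TestQuantileThreshold:
    def test_type7_quantile_on_one_to_ten(self, top_rule):
        assert top_rule.value == pytest.approx(8.2)

    def test_median_at_half(self):
        rule = sel.quantile_threshold([1.0, 2.0, 3.0, 4.0, 5.0], tau=0.5)
        assert rule.value == 3.0

    def test_bottom_direction_uses_mirrored_level(self):
        rule = sel.quantile_threshold(np.arange(1.0, 11.0), tau=0.8, direction="bottom")
        assert rule.value == pytest.approx(2.8)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.2])
    def test_tau_outside_open_interval_rejected(self, tau):
        with pytest.raises(ValueError):
            sel.quantile_threshold(np.arange(10.0), tau=tau)


class TestLabels:
    def test_strictly_above_threshold_is_top(self):
        rule = sel.ThresholdRule("phenotype", 8.0)
        np.testing.assert_array_equal(sel.observed_labels([7.0, 9.0], rule), [0, 1])

    def test_equality_is_not_top(self):
        rule = sel.ThresholdRule("phenotype", 8.0)
        assert sel.observed_labels([8.0], rule)[0] == 0

    def test_exactly_two_positives_at_eighty_percent(self, top_rule):
        labels = sel.observed_labels(np.arange(1.0, 11.0), top_rule)
        assert labels.sum() == 2

    def test_bottom_direction_reverses_inequality(self):
        rule = sel.ThresholdRule("phenotype", 2.8, direction="bottom")
        labels = sel.observed_labels(np.arange(1.0, 11.0), rule)
        np.testing.assert_array_equal(labels, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0])


class TestClassifyR:
    def test_strict_threshold_comparison(self):
        rule = sel.ThresholdRule("phenotype", 8.0)
        np.testing.assert_array_equal(sel.classify_r([8.5, 7.9], rule), [1, 0])

    def test_all_below_threshold_gives_no_positives(self):
        rule = sel.ThresholdRule("phenotype", 8.0)
        assert sel.classify_r([1.0, 2.0, 3.0], rule).sum() == 0

    def test_shrunken_predictions_underselect_top_lines(self):
        # the R-method bias: shrinkage pulls tail predictions below Y_tau
        y = np.arange(1.0, 11.0)
        rule = sel.quantile_threshold(y, tau=0.8)
        shrunk = 0.5 * y
        observed = sel.observed_labels(y, rule)
        predicted = sel.classify_r(shrunk, rule)
        assert predicted.sum() < observed.sum()


class TestClassifyRC:
    def test_rank_matching_hand_example(self):
        rule = sel.ThresholdRule("phenotype", 8.0)
        out = sel.classify_rc([10.0, 9.0, 5.0, 4.0, 3.0], [9.5, 4.8, 8.7, 3.9, 2.0],
                              rule, line_ids=list("abcde"))
        np.testing.assert_array_equal(out.observed, [1, 1, 0, 0, 0])
        np.testing.assert_array_equal(out.predicted, [1, 0, 1, 0, 0])

    def test_perfect_ranking_matches_exactly(self):
        rule = sel.ThresholdRule("phenotype", 8.0)
        y = np.arange(1.0, 11.0)
        out = sel.classify_rc(y, y * 0.5, rule)  # monotone transform preserves ranks
        np.testing.assert_array_equal(out.predicted, out.observed)

    def test_no_observed_positives_means_no_predicted(self):
        rule = sel.ThresholdRule("phenotype", 100.0)
        out = sel.classify_rc([1.0, 2.0], [5.0, 6.0], rule)
        assert out.predicted.sum() == 0

    def test_equal_count_invariant_and_tie_break(self):
        rule = sel.ThresholdRule("phenotype", 2.5)
        out = sel.classify_rc([3.0, 1.0, 2.0, 4.0], [7.0, 5.0, 5.0, 5.0], rule)
        assert out.predicted.sum() == out.observed.sum() == 2
        # tie at rank 2 among equal scores broken by input order
        np.testing.assert_array_equal(out.predicted, [1, 1, 0, 0])

    def test_permutation_invariance_up_to_tie_break(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=30)
        pred = rng.normal(size=30)
        rule = sel.quantile_threshold(y, tau=0.8)
        perm = rng.permutation(30)
        out = sel.classify_rc(y, pred, rule)
        out_p = sel.classify_rc(y[perm], pred[perm], rule)
        np.testing.assert_array_equal(out.predicted[perm], out_p.predicted)


class TestRegressionOptimizer:
    def test_separating_midpoint_found_by_enumeration(self):
        base = sel.ThresholdRule("phenotype", 3.0)
        rule = sel.optimize_regression_threshold(
            [([1.0, 2.0, 3.0, 4.0, 5.0], [0, 0, 0, 1, 1])], base)
        assert rule.value == pytest.approx(3.5)
        assert rule.provenance == "optimized"
        assert rule.fold_values == (3.5,)

    def test_single_class_fold_skipped(self):
        base = sel.ThresholdRule("phenotype", 3.0)
        rule = sel.optimize_regression_threshold(
            [([1.0, 2.0], [1, 1]), ([1.0, 2.0, 3.0, 4.0, 5.0], [0, 0, 0, 1, 1])], base)
        assert rule.fold_values == (3.5,)

    def test_mean_of_fold_optima(self):
        base = sel.ThresholdRule("phenotype", 4.0)
        rule = sel.optimize_regression_threshold(
            [([1.0, 2.0, 3.0, 4.0, 5.0], [0, 0, 0, 1, 1]),
             ([2.0, 3.0, 4.0, 5.0, 6.0], [0, 0, 0, 1, 1])], base)
        assert rule.value == pytest.approx((3.5 + 4.5) / 2)

    def test_all_degenerate_falls_back_to_base_with_warning(self):
        base = sel.ThresholdRule("phenotype", 3.0)
        with pytest.warns(sel.DegenerateFoldsWarning):
            rule = sel.optimize_regression_threshold([([1.0, 2.0], [0, 0])], base)
        assert rule is base

    def test_objective_never_worse_than_base_rule(self):
        rng = np.random.default_rng(2)
        base_val = 0.8

        def fold_objective(scores, labels, cutoff):
            pred = (scores > cutoff).astype(int)
            sens = pred[labels == 1].mean()
            spec = 1 - pred[labels == 0].mean()
            return (sens - spec) ** 2

        for _ in range(20):
            scores = rng.normal(size=25)
            labels = (scores + rng.normal(size=25)) > base_val
            if labels.all() or not labels.any():
                continue
            folds = [(scores, labels.astype(int))]
            base = sel.ThresholdRule("phenotype", base_val)
            rule = sel.optimize_regression_threshold(folds, base)
            assert fold_objective(scores, labels, rule.fold_values[0]) <= \
                fold_objective(scores, labels, base_val) + 1e-12


class TestProbabilityOptimizer:
    def test_half_preferred_among_zero_objective_candidates(self):
        rule = sel.optimize_probability_threshold(
            [([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])])
        assert rule.value == pytest.approx(0.5)

    def test_clustered_probabilities_push_threshold_below_half(self):
        # positives cluster at 0.3-0.4, negatives at 0.05-0.2: balancing
        # sensitivity and specificity needs a cutoff below one half
        probs = [0.05, 0.10, 0.15, 0.20, 0.30, 0.35, 0.40]
        labels = [0, 0, 0, 0, 1, 1, 1]
        rule = sel.optimize_probability_threshold([(probs, labels)])
        assert rule.value < 0.5

    def test_perfect_separation_gives_zero_objective(self):
        rule = sel.optimize_probability_threshold(
            [([0.2, 0.3, 0.7, 0.8], [0, 0, 1, 1])])
        pred = (np.array([0.2, 0.3, 0.7, 0.8]) > rule.value).astype(int)
        np.testing.assert_array_equal(pred, [0, 0, 1, 1])

    def test_result_lies_in_unit_interval(self):
        rng = np.random.default_rng(3)
        probs = rng.uniform(0.01, 0.99, size=40)
        labels = (probs > 0.6).astype(int)
        rule = sel.optimize_probability_threshold([(probs, labels)])
        assert 0.0 < rule.value < 1.0


class TestAdjustedPredictions:
    def test_rescaling_reproduces_optimized_rule(self):
        base = sel.ThresholdRule("phenotype", 4.0)
        opt = sel.ThresholdRule("phenotype", 2.0, provenance="optimized")
        adj = sel.adjusted_predictions([2.0, 4.0], base, opt)
        np.testing.assert_allclose(adj, [4.0, 8.0])
        lab_adj = sel.classify_r(adj, base)
        lab_opt = sel.classify_r([2.0, 4.0], opt)
        np.testing.assert_array_equal(lab_adj, lab_opt)

    def test_equal_thresholds_leave_predictions_unchanged(self):
        base = sel.ThresholdRule("phenotype", 3.0)
        opt = sel.ThresholdRule("phenotype", 3.0, provenance="optimized")
        np.testing.assert_array_equal(sel.adjusted_predictions([1.0, 2.0], base, opt),
                                      [1.0, 2.0])

    def test_zero_optimum_rejected_and_sign_flip_warns(self):
        base = sel.ThresholdRule("phenotype", 4.0)
        with pytest.raises(ValueError):
            sel.adjusted_predictions([1.0], base, sel.ThresholdRule("phenotype", 0.0))
        with pytest.warns(UserWarning, match="opposite signs"):
            sel.adjusted_predictions([1.0], base, sel.ThresholdRule("phenotype", -2.0))


class TestSimpleTuningScores:
    def test_partition_into_ten_folds(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=200)
        labels = (scores > 0.8).astype(int)
        folds = sel.simple_tuning_scores(scores, labels, k_folds=10, seed=1)
        assert len(folds) == 10
        assert sum(len(s) for s, _ in folds) == 200
        assert all(len(s) == 20 for s, _ in folds)

    def test_same_seed_same_partition(self):
        scores = np.arange(40.0)
        labels = (scores > 30).astype(int)
        f1 = sel.simple_tuning_scores(scores, labels, seed=9)
        f2 = sel.simple_tuning_scores(scores, labels, seed=9)
        for (s1, l1), (s2, l2) in zip(f1, f2):
            np.testing.assert_array_equal(s1, s2)
            np.testing.assert_array_equal(l1, l2)

    def test_too_small_folds_rejected(self):
        with pytest.raises(ValueError, match="2 lines per fold"):
            sel.simple_tuning_scores(np.arange(15.0), np.zeros(15, int), k_folds=10, seed=1)

    def test_simple_threshold_tracks_original_threshold(self):
        # paired comparison of the once-fitted Simple tuning against the
        # per-fold refitting Original tuning on one outer fold each
        gaps, iqrs = [], []
        settings = MCMCSettings(500, 100, 1, seed=0)
        for rep in range(10):
            y, grm, _ = simulate_slice(500 + rep, n_lines=300, n_markers=500)
            folds = make_folds(300, 5, seed=rep)
            test_idx = folds[0]
            train_idx = np.setdiff1d(np.arange(300), test_idx)
            plan = CVPlan(seed=rep)
            res_o = evaluate_fold("RO", "O", y, grm, train_idx, test_idx,
                                  settings=settings, plan=plan)
            res_s = evaluate_fold("RO", "S", y, grm, train_idx, test_idx,
                                  settings=settings, plan=plan)
            gaps.append(abs(res_o.rule.value - res_s.rule.value))
            iqrs.append(np.subtract(*np.percentile(y[train_idx], [75, 25])))
        assert np.mean(gaps) < 0.25 * np.mean(iqrs)


def test_threshold_rule_json_round_trip():
    rule = sel.ThresholdRule("probability", 0.45, tau=0.8, provenance="optimized",
                             fold_values=(0.4, 0.5))
    back = sel.ThresholdRule.from_json(rule.to_json())
    assert back == rule


def test_fold_values_must_average_to_value():
    with pytest.raises(ValueError, match="mean"):
        sel.ThresholdRule("phenotype", 1.0, fold_values=(0.0, 1.0))
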