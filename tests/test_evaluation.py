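"""Metrics against independent oracles; nested CV protocol behaviour."""

import numpy as np
import pytest

from popisk import (
    FAST_GRID,
    GridSpec,
    builtin_table,
    compute_metrics,
    confusion,
    learning_curve,
    metrics_from_scores,
    nested_cv,
    baseline_property_svm,
    enrichment_dataset,
    planted_rule_dataset,
    position_swap_dataset,
    shuffled_null_dataset,
)
from popisk.evaluation import ConfusionCounts

#: Small grid keeping routine protocol tests fast; the protocol itself
#: (10x10 nested stratified CV, AUC selection, tie-breaks) is untouched.
TINY_GRID = GridSpec(Cs=(1.0,), ds=(1, 5, 9))


def auc_by_enumeration(scores, truth):
    """Oracle: count concordant positive/negative pairs, half credit for ties."""
    pos = [s for s, y in zip(scores, truth) if y == 1]
    neg = [s for s, y in zip(scores, truth) if y == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def mcc_by_formula(tp, tn, fp, fn):
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    return 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1.0, -1.0], [1, -1])
        assert (c.FP, c.FN) == (0, 0)

    def test_zero_scores_all_negative(self):
        c = confusion([0.0, 0.0, 0.0], [1, 1, -1])
        assert c.TP == 0 and c.FN == 2 and c.TN == 1

    def test_mixed_hand_enumeration(self):
        scores = [0.5, -0.2, 0.1, -0.9, 0.0]
        truth = [1, 1, -1, -1, 1]
        c = confusion(scores, truth)
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 1, 2)
        assert c.total == 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestMetrics:
    def test_perfect_separation(self):
        scores = np.array([2.0, 1.0, -1.0, -2.0])
        truth = np.array([1, 1, -1, -1])
        m = metrics_from_scores(scores, truth)
        assert (m.ACC, m.MCC, m.AUC) == (1.0, 1.0, 1.0)

    def test_balanced_coin_flip(self):
        m = compute_metrics(ConfusionCounts(TP=25, TN=25, FP=25, FN=25))
        assert m.ACC == 0.5 and m.MCC == 0.0

    def test_worked_mcc_case(self):
        m = compute_metrics(ConfusionCounts(TP=3, TN=2, FP=1, FN=2))
        assert m.ACC == pytest.approx(0.625)
        assert m.MCC == pytest.approx(4 / np.sqrt(240))

    def test_worked_auc_case(self):
        scores = np.array([0.9, 0.8, 0.4, 0.7, 0.3])
        truth = np.array([1, 1, 1, -1, -1])
        m = metrics_from_scores(scores, truth)
        assert m.AUC == pytest.approx(5 / 6)

    def test_random_vectors_match_oracles_exactly(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            truth = rng.choice([-1, 1], size=n)
            if len(np.unique(truth)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            m = metrics_from_scores(scores, truth)
            c = confusion(scores, truth)
            assert m.AUC == pytest.approx(auc_by_enumeration(scores, truth), abs=1e-12)
            assert m.MCC == pytest.approx(mcc_by_formula(c.TP, c.TN, c.FP, c.FN), abs=1e-12)
            assert m.ACC == pytest.approx((c.TP + c.TN) / n, abs=1e-12)

    def test_mcc_degenerate_denominator_is_zero(self):
        m = compute_metrics(ConfusionCounts(TP=5, TN=0, FP=5, FN=0))
        assert m.MCC == 0.0

    def test_mcc_sign_flips_with_predictions(self):
        m1 = compute_metrics(ConfusionCounts(TP=8, TN=7, FP=2, FN=3))
        m2 = compute_metrics(ConfusionCounts(TP=3, TN=2, FP=7, FN=8))
        assert m2.MCC == pytest.approx(-m1.MCC)

    def test_mcc_invariant_under_class_swap(self):
        m1 = compute_metrics(ConfusionCounts(TP=8, TN=7, FP=2, FN=3))
        m2 = compute_metrics(ConfusionCounts(TP=7, TN=8, FP=3, FN=2))
        assert m2.MCC == pytest.approx(m1.MCC)


class TestNestedCV:
    def test_fold_bookkeeping_and_report_shape(self):
        data = planted_rule_dataset(30, 30, seed=7)
        rep = nested_cv(data, TINY_GRID, n_runs=1, seed=4)
        assert len(rep.folds) == 10
        assert set(rep.folds["fold"]) == set(range(10))
        sizes = rep.folds.groupby("fold").size()
        assert (sizes == 1).all()
        assert rep.summary["grid"]["d"] == [1, 5, 9]

    def test_planted_rule_recovered(self):
        data = planted_rule_dataset(100, 100, seed=1)
        rep = nested_cv(data, TINY_GRID, n_runs=1, seed=0)
        assert rep.mean.AUC >= 0.95

    def test_shuffled_labels_near_chance(self):
        null = shuffled_null_dataset(75, 75, seed=9)
        rep = nested_cv(null, GridSpec(Cs=(1.0,), ds=(5,)), n_runs=2, seed=0)
        assert 0.35 <= rep.mean.AUC <= 0.65

    def test_run_sd_small_on_fixed_dataset(self):
        data = enrichment_dataset(75, 75, seed=13)
        rep = nested_cv(data, GridSpec(Cs=(1.0,), ds=(9,)), n_runs=3, seed=2)
        assert rep.sd.AUC < 0.05

    def test_outer_estimate_close_to_large_holdout(self):
        """Nested-CV outer AUC tracks a large independent test set."""
        for seed in (0, 1):
            data = planted_rule_dataset(50, 50, seed=seed)
            rep = nested_cv(data, TINY_GRID, n_runs=1, seed=seed)
            holdout = planted_rule_dataset(200, 200, seed=seed + 100)
            from popisk import KernelSpec, predict, train
            model = train(data, KernelSpec(d=9), C=1.0)
            m = metrics_from_scores(predict(model, holdout.peptides).scores,
                                    holdout.labels)
            assert abs(rep.mean.AUC - m.AUC) <= 0.05

    def test_deterministic_given_seed(self):
        data = planted_rule_dataset(30, 30, seed=3)
        g = GridSpec(Cs=(1.0,), ds=(5,))
        r1 = nested_cv(data, g, n_runs=1, seed=8)
        r2 = nested_cv(data, g, n_runs=1, seed=8)
        assert r1.folds.equals(r2.folds)

    def test_degree_above_length_rejected(self):
        data = planted_rule_dataset(30, 30, seed=3)
        with pytest.raises(ValueError):
            nested_cv(data, GridSpec(Cs=(1.0,), ds=(10,)), n_runs=1, seed=0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(Cs=())


class TestLearningCurve:
    def test_monotone_benefit_and_determinism(self):
        data = planted_rule_dataset(150, 150, seed=21)
        t1 = learning_curve(data, sizes=[20, 150], seed=5)
        t2 = learning_curve(data, sizes=[20, 150], seed=5)
        assert t1.equals(t2)
        assert t1.loc[t1["size"] == 150, "test_AUC"].item() >= \
            t1.loc[t1["size"] == 20, "test_AUC"].item()

    def test_full_pool_equals_plain_split_run(self):
        data = planted_rule_dataset(60, 60, seed=2)
        t = learning_curve(data, sizes=[60], seed=1)
        assert len(t) == 1 and t["size"].item() == 60
        assert t["C"].item() == 1.0 and t["d"].item() == 9

    def test_oversized_request_rejected(self):
        data = planted_rule_dataset(30, 30, seed=2)
        with pytest.raises(ValueError):
            learning_curve(data, sizes=[45], seed=0)  # pool is 30


class TestPropertyBaseline:
    def test_composition_signal_is_learnable(self):
        """Labels driven by mean hydrophobicity are easy for the baseline."""
        from popisk import LabeledDataset
        from popisk.physchem import KD_HYDROPATHY
        rng = np.random.default_rng(6)
        from conftest import random_peptides
        peps = random_peptides(rng, 120)
        means = np.array([np.mean([KD_HYDROPATHY[a] for a in p]) for p in peps])
        labels = np.where(means > np.median(means), 1, -1)
        # drop ties at the median to keep the rule clean
        keep = means != np.median(means)
        data = LabeledDataset([p for p, k in zip(peps, keep) if k], labels[keep])
        rep = baseline_property_svm(
            data, builtin_table(),
            GridSpec(Cs=(1.0, 4.0), gammas=(0.25, 1.0)), n_runs=1, seed=0)
        assert rep.mean.AUC >= 0.9

    def test_positional_signal_is_invisible(self):
        """Composition-matched position-swap data defeats the mean-property
        baseline while the string kernel separates it (the core contrast)."""
        data = position_swap_dataset(60, 60, seed=17)
        base = baseline_property_svm(
            data, builtin_table(),
            GridSpec(Cs=(1.0,), gammas=(0.25, 1.0)), n_runs=1, seed=0)
        assert base.mean.AUC <= 0.65
        wd = nested_cv(data, GridSpec(Cs=(1.0,), ds=(9,)), n_runs=1, seed=0)
        assert wd.mean.AUC >= 0.9

    def test_gamma_zero_limit_flat_kernel(self):
        from popisk.physchem import encode_mean_properties
        data = position_swap_dataset(10, 10, seed=3)
        X = encode_mean_properties(data.peptides, builtin_table()).to_numpy()
        sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        assert np.allclose(np.exp(-1e-12 * sq), 1.0, atol=1e-9)
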