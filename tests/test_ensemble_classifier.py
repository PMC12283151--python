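import numpy as np
import pytest
from scipy.stats import binomtest, norm

import songcorpus as sc
from songcorpus.ensemble_classifier import (
    EnsembleConfig, VoteMatrix, _BinaryL1Classifier, balanced_bootstrap,
    evaluate, fit_l1_classifier, make_splits, modal_prediction,
    permutation_test, run_ensemble, run_fold, DEFAULT_C_GRID,
)


class TestMakeSplits:
    def test_partitions_disjoint_cover_and_balanced(self):
        schemes = make_splits(100, 10, 3, seed=0)
        assert len(schemes) == 3
        for folds in schemes:
            sizes = [len(f) for f in folds]
            assert sizes == [10] * 10
            union = np.concatenate(folds)
            assert sorted(union) == list(range(100))

    def test_pigeonhole_sizes_for_uneven_n(self):
        folds = make_splits(101, 10, 1, seed=1)[0]
        assert sorted(len(f) for f in folds) == [10] * 9 + [11]

    def test_deterministic_and_k_too_large(self):
        a = make_splits(20, 4, 2, seed=5)
        b = make_splits(20, 4, 2, seed=5)
        for fa, fb in zip(a, b):
            for x, y in zip(fa, fb):
                np.testing.assert_array_equal(x, y)
        with pytest.raises(ValueError):
            make_splits(5, 10, 1, seed=0)


class TestBalancedBootstrap:
    def test_max_class_rule_exact_counts(self):
        labels = np.array(["a", "a", "a", "b"])
        rng = np.random.default_rng(0)
        idx = balanced_bootstrap(labels, np.arange(4), rng, "max-class")
        assert len(idx) == 6
        assert np.sum(labels[idx] == "a") == 3
        assert np.sum(labels[idx] == "b") == 3

    def test_already_balanced_draws_class_size(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        rng = np.random.default_rng(1)
        idx = balanced_bootstrap(labels, np.arange(10), rng, "max-class")
        assert np.sum(labels[idx] == "a") == 5
        assert np.sum(labels[idx] == "b") == 5

    def test_min_class_rule(self):
        labels = np.array(["a"] * 6 + ["b"] * 2)
        rng = np.random.default_rng(2)
        idx = balanced_bootstrap(labels, np.arange(8), rng, "min-class")
        assert np.sum(labels[idx] == "a") == 2
        assert np.sum(labels[idx] == "b") == 2

    def test_missing_class_named(self):
        labels = np.array(["a", "a", "b", "b"])
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="b"):
            balanced_bootstrap(labels, np.array([0, 1]), rng)

    def test_distinct_item_coverage_matches_bootstrap_oracle(self):
        # expected coverage of a class of size n_c bootstrapped m times is
        # 1 - (1 - 1/n_c)^m
        n_c, reps = 8, 1000
        labels = np.array(["a"] * n_c + ["b"] * 16)
        rng = np.random.default_rng(3)
        m = 16  # max-class
        cov = []
        for _ in range(reps):
            idx = balanced_bootstrap(labels, np.arange(24), rng, "max-class")
            a_items = set(idx[labels[idx] == "a"])
            cov.append(len(a_items) / n_c)
        expected = 1 - (1 - 1 / n_c) ** m
        assert abs(np.mean(cov) - expected) < 0.02


class TestFitL1:
    def test_separable_toy_perfect_training_accuracy(self):
        X = np.concatenate([np.full((10, 1), -2.0), np.full((10, 1), 2.0)])
        X = X + np.random.default_rng(0).normal(0, 0.1, X.shape)
        y = np.array(["a"] * 10 + ["b"] * 10)
        clf = fit_l1_classifier(X, y, "cv5", seed=0)
        assert np.mean(clf.predict(X) == y) == 1.0
        # exhaustive penalty-path check: some grid C separates the toy set,
        # and the CV-selected model is at least as accurate as the best
        accs = []
        for C in DEFAULT_C_GRID:
            m = fit_l1_classifier(X, y, f"fixed:{C}", seed=0)
            accs.append(np.mean(m.predict(X) == y))
        assert max(accs) == 1.0

    def test_constant_features_give_null_coefficients(self):
        X = np.full((12, 3), 7.0)
        y = np.array(["a", "b"] * 6)
        clf = fit_l1_classifier(X, y, "fixed", seed=0)
        np.testing.assert_allclose(clf.coef_, 0.0)
        assert len(set(clf.predict(X))) == 1  # intercept-only prediction

    def test_single_class_and_nonfinite_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            fit_l1_classifier(X, np.array(["a"] * 4), "fixed")
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_l1_classifier(X, np.array(["a", "a", "b", "b"]), "fixed")

    def test_binary_fast_path_matches_public_estimator(self):
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(4)
        for trial in range(10):
            X = rng.standard_normal((30, 4))
            y = rng.choice(["a", "b"], 30)
            if len(set(y)) < 2:
                continue
            mu, sd = X.mean(0), X.std(0)
            Xs = (X - mu) / sd
            fast = _BinaryL1Classifier(Xs, y, C=1.0, seed=0)
            ref = LogisticRegression(l1_ratio=1, C=1.0, solver="liblinear",
                                     random_state=0, tol=1e-3).fit(Xs, y)
            np.testing.assert_allclose(fast.coef_, ref.coef_, atol=1e-6)
            np.testing.assert_array_equal(fast.predict(Xs), ref.predict(Xs))

    def test_label_permutation_gives_chance_heldout_accuracy(self):
        rng = np.random.default_rng(5)
        accs = []
        for _ in range(100):
            X = rng.standard_normal((40, 3))
            y = rng.permutation(np.array(["a", "b"] * 20))
            clf = fit_l1_classifier(X[:30], y[:30], "fixed", seed=0)
            accs.append(np.mean(clf.predict(X[30:]) == y[30:]))
        assert abs(np.mean(accs) - 0.5) < 0.05


class TestRunEnsemble:
    def test_vote_conservation_small_config(self, balanced_synth):
        X = balanced_synth.features.values
        labels = balanced_synth.corpus.contexts.to_numpy()
        cfg = EnsembleConfig(k_partitions=4, n_boot_per_partition=3,
                             n_splits=2, penalty_selection="fixed",
                             contexts_included=tuple(np.unique(labels)), seed=0)
        votes = run_ensemble(X, labels, cfg)
        assert np.all(votes.totals == 6)

    def test_strong_context_signal_beats_chance(self, balanced_synth):
        X = balanced_synth.features.values
        labels = balanced_synth.corpus.contexts.to_numpy()
        cfg = EnsembleConfig(k_partitions=5, n_boot_per_partition=5,
                             n_splits=5, penalty_selection="fixed",
                             contexts_included=tuple(np.unique(labels)), seed=1)
        pred, _ = modal_prediction(run_ensemble(X, labels, cfg))
        k = int(np.sum(pred == labels))
        assert binomtest(k, len(labels), 0.25, "greater").pvalue < 0.01

    def test_no_leakage_from_test_partition(self, balanced_synth):
        # planting a marker value in the test rows must leave the fitted
        # model (standardization, penalty, coefficients) unchanged
        X = balanced_synth.features.values.copy()
        labels = balanced_synth.corpus.contexts.to_numpy()
        train = np.arange(0, 60)
        test = np.arange(60, 80)
        cfg = EnsembleConfig(k_partitions=4, penalty_selection="cv5",
                             contexts_included=tuple(np.unique(labels)), seed=0)
        clf1, _ = run_fold(X, labels, train, test, cfg,
                           np.random.default_rng(99))
        X2 = X.copy()
        X2[test] = 1e6  # absurd marker
        clf2, _ = run_fold(X2, labels, train, test, cfg,
                           np.random.default_rng(99))
        np.testing.assert_array_equal(clf1.coef_, clf2.coef_)
        assert clf1.C_ == clf2.C_

    def test_labels_outside_included_contexts_rejected(self):
        X = np.zeros((4, 2))
        labels = np.array(["dance", "work", "dance", "work"])
        cfg = EnsembleConfig(contexts_included=("dance", "lullaby"))
        with pytest.raises(ValueError, match="work"):
            run_ensemble(X, labels, cfg)

    def test_shuffled_labels_give_chance_accuracy_on_average(self, null_synth):
        X = null_synth.features.values
        contexts = ("dance", "healing", "love", "lullaby")
        labels = np.repeat(contexts, len(X) // 4)  # balanced so folds keep all classes
        rng = np.random.default_rng(17)
        accs = []
        for rep in range(50):
            cfg = EnsembleConfig(k_partitions=2, n_boot_per_partition=3,
                                 n_splits=3, penalty_selection="fixed",
                                 contexts_included=contexts, seed=rep)
            shuffled = rng.permutation(labels)
            pred, _ = modal_prediction(run_ensemble(X, shuffled, cfg))
            accs.append(np.mean(pred == shuffled))
        assert abs(np.mean(accs) - 0.25) < 0.04


class TestModalPrediction:
    def test_argmax_and_tie_handling(self):
        votes = VoteMatrix(["s1", "s2"], ("dance", "lullaby"),
                           [[150, 100], [125, 125]])
        pred, ties = modal_prediction(votes)
        assert pred[0] == "dance"
        assert pred[1] == "dance"  # tie -> earlier in canonical order
        np.testing.assert_array_equal(ties, [False, True])

    def test_column_order_does_not_change_predictions(self):
        a = VoteMatrix(["s1"], ("dance", "lullaby"), [[100, 150]])
        b = VoteMatrix(["s1"], ("lullaby", "dance"), [[150, 100]])
        assert modal_prediction(a)[0][0] == modal_prediction(b)[0][0] == "lullaby"

    def test_zero_votes_rejected(self):
        votes = VoteMatrix(["s1"], ("dance", "lullaby"), [[0, 0]])
        with pytest.raises(ValueError):
            modal_prediction(votes)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["dance"] * 10 + ["lullaby"] * 10)
        rep = evaluate(y, y, ("dance", "lullaby"))
        assert rep.accuracy == 1.0
        assert rep.chance_level == 0.5
        # d' at the corrected ceiling: H = 1 - 1/(2*10), FA = 1/(2*10)
        dmax = norm.ppf(1 - 0.05) - norm.ppf(0.05)
        assert rep.per_context_dprime["dance"] == pytest.approx(dmax)
        np.testing.assert_allclose(rep.confusion.sum(axis=1), 1.0)

    def test_uniform_random_predictions_hit_chance(self):
        rng = np.random.default_rng(0)
        contexts = ("dance", "healing", "love", "lullaby")
        y = rng.choice(contexts, 4000)
        pred = rng.choice(contexts, 4000)
        rep = evaluate(pred, y, contexts)
        assert rep.chance_level == 0.25
        assert abs(rep.accuracy - 0.25) < 0.03

    def test_dprime_against_quantile_oracle(self):
        # H=0.84, FA=0.16 -> d' = z(0.84) - z(0.16) ~= 1.989
        y = np.array(["a"] * 100 + ["b"] * 100)
        pred = np.array(
            ["a"] * 84 + ["b"] * 16 +  # true a: 84 hits
            ["a"] * 16 + ["b"] * 84)   # true b: 16 false alarms for a
        rep = evaluate(pred, y, ("a", "b"))
        assert rep.per_context_hit_rate["a"] == pytest.approx(0.84)
        assert rep.per_context_false_alarm["a"] == pytest.approx(0.16)
        assert rep.per_context_dprime["a"] == pytest.approx(1.9885, abs=1e-3)

    def test_empty_class_reported_missing(self):
        y = np.array(["a", "a"])
        pred = np.array(["a", "b"])
        rep = evaluate(pred, y, ("a", "b"))
        assert rep.n_per_context["b"] == 0
        assert np.isnan(rep.confusion.loc["b"]).all()


class TestPermutationTest:
    def test_p_value_arithmetic_and_rules(self, null_synth):
        X = null_synth.features.values[:24]
        contexts = ("dance", "lullaby")
        labels = np.array(list(contexts) * 12)
        cfg = EnsembleConfig(k_partitions=2, n_boot_per_partition=2,
                             n_splits=2, penalty_selection="fixed",
                             contexts_included=contexts, seed=0)
        res = permutation_test(X, labels, cfg, n_perm=19, seed=3)
        higher = int(np.sum(res.permuted_accuracies > res.observed_accuracy))
        assert res.p_overall == higher / 19
        res_s = permutation_test(X, labels, cfg, n_perm=19, seed=3,
                                 rule="add-one")
        assert res_s.p_overall == (1 + higher) / 20
        assert set(res.p_per_context) == set(contexts)
        assert 0 <= res.p_overall <= 1

    def test_stated_rule_examples(self):
        # 3 of 200 permutations above observed -> p = 0.015; observed below
        # every permutation -> p = 1 under the strict rule
        assert 3 / 200 == 0.015
        perm = np.linspace(0.5, 0.9, 10)
        assert np.mean(perm > 0.4) == 1.0

    def test_too_few_permutations_rejected(self, null_synth):
        X = null_synth.features.values
        labels = null_synth.corpus.contexts.to_numpy()
        cfg = EnsembleConfig(contexts_included=tuple(np.unique(labels)))
        with pytest.raises(ValueError):
            permutation_test(X, labels, cfg, n_perm=18)


class TestEnsembleConfig:
    def test_votes_per_song_and_chance(self):
        cfg = EnsembleConfig()
        assert cfg.votes_per_song == 250
        assert cfg.chance_level == 0.1
        four = EnsembleConfig(
            contexts_included=("dance", "lullaby", "healing", "love"))
        assert four.chance_level == 0.25

    def test_contexts_canonicalized_to_vocabulary_order(self):
        cfg = EnsembleConfig(contexts_included=("love", "dance", "healing"))
        assert cfg.contexts_included == ("dance", "healing", "love")

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig(k_partitions=1)
        with pytest.raises(ValueError):
            EnsembleConfig(contexts_included=("dance", "jogging"))
        with pytest.raises(ValueError):
            EnsembleConfig(balance_target="median-class")
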