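"""Cross-validation engine, metrics, Youden point, information gain, SMOTE."""

import math

import numpy as np
import pandas as pd
import pytest

import lctox as lx
from lctox.feature_extraction import amp_descriptor
from lctox.ml_harness import balance_training_fold, expand_value_levels


def indicator_matrix(values_by_col, labels):
    """Small categorical FeatureMatrix over fake AMP columns."""
    idx = pd.Index([f"s{i}" for i in range(len(labels))], name="sequence_id")
    data = pd.DataFrame({f"AMP:{k + 1}": v for k, v in enumerate(values_by_col)},
                        index=idx).astype(str)
    descs = {f"AMP:{k + 1}": amp_descriptor(k + 1) for k in range(len(values_by_col))}
    return lx.FeatureMatrix(data, pd.Series(labels, index=idx, name="label"), descs)


class TestComputeMetrics:
    def test_hand_arithmetic_example(self):
        m = lx.compute_metrics(3, 2, 8, 1)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(11 / 14)
        assert m["balanced_accuracy"] == pytest.approx(0.775)
        assert m["f1"] == pytest.approx(2 * 3 / (6 + 2 + 1))

    def test_undefined_metric_is_missing_not_zero(self):
        m = lx.compute_metrics(0, 2, 8, 0)  # no positives at all
        assert m["sensitivity"] is None
        assert m["balanced_accuracy"] is None

    def test_constant_scores_auc_half(self):
        m = lx.compute_metrics(1, 1, 1, 1, scores=[0.5] * 4, labels=[1, 0, 1, 0])
        assert m["auc"] == pytest.approx(0.5)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        a1 = lx.compute_metrics(1, 1, 1, 1, scores, labels)["auc"]
        a2 = lx.compute_metrics(1, 1, 1, 1, np.sqrt(scores) ** 0.3, labels)["auc"]
        assert a1 == pytest.approx(a2)

    def test_auc_equals_rank_statistic_oracle(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=40)
        labels = np.array([0, 1] * 20)
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert lx.compute_metrics(1, 1, 1, 1, scores, labels)["auc"] == \
            pytest.approx(wins / (len(pos) * len(neg)))


class TestYouden:
    def test_printed_operating_point(self):
        assert lx.youden_index(0.76, 0.82) == pytest.approx(0.58)

    def test_perfect_separation(self):
        _, j, se, sp = lx.youden_optimize([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert (j, se, sp) == (1.0, 1.0, 1.0)

    def test_brute_force_maximality(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            scores = rng.uniform(size=n).round(2)
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            thr, j, se, sp = lx.youden_optimize(scores, labels)
            assert j == pytest.approx(se + sp - 1)
            best = max(
                ((scores >= c) & (labels == 1)).sum() / labels.sum()
                + (~(scores >= c) & (labels == 0)).sum() / (1 - labels).sum() - 1
                for c in scores)
            assert j == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lx.youden_optimize([0.4, 0.6], [1, 1])


def test_random_classifier_binomial_point_probability():
    assert lx.random_classifier_probability(10, 12) == pytest.approx(
        math.comb(12, 10) / 2 ** 12)


class TestInfoGain:
    def test_label_identical_feature_one_bit(self):
        x = ["a", "b"] * 10
        y = [1, 0] * 10
        assert lx.info_gain(x, y) == pytest.approx(1.0)

    def test_constant_feature_zero_and_removed(self):
        m = indicator_matrix([["z"] * 10, ["a", "b"] * 5],
                             ["tox", "nox"] * 5)
        ranked = lx.info_gain_rank(m, cutoff=0.01)
        assert all("1-" not in r.descriptor.name for r in ranked)
        assert any(r.descriptor.name.startswith("2-") for r in ranked)

    def test_three_level_feature_hand_entropy(self):
        x = ["a", "a", "a", "a", "b", "b", "b", "c", "c", "c"]
        y = [1, 1, 1, 0, 0, 0, 0, 1, 0, 0]

        def h(*counts):
            tot = sum(counts)
            return -sum(c / tot * math.log2(c / tot) for c in counts if c)

        expected = h(4, 6) - (0.4 * h(3, 1) + 0.3 * h(0, 3) + 0.3 * h(1, 2))
        assert lx.info_gain(x, y) == pytest.approx(expected, abs=1e-12)

    def test_ig_nonnegative_and_bounded_by_label_entropy(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        for _ in range(20):
            x = rng.choice(list("abcd"), 50)
            ig = lx.info_gain(x, y)
            assert -1e-12 <= ig <= lx.info_gain(y, y) + 1e-12

    def test_ranks_consistent(self, planted_matrix):
        ranked = lx.info_gain_rank(planted_matrix)
        assert [r.general_rank for r in ranked] == list(range(1, len(ranked) + 1))
        igs = [r.info_gain_bits for r in ranked]
        assert igs == sorted(igs, reverse=True)
        for fam in {r.descriptor.family for r in ranked}:
            fr = [r.family_rank for r in ranked if r.descriptor.family == fam]
            assert fr == list(range(1, len(fr) + 1))


class TestGrid:
    def test_exactly_56_experiments(self):
        grid = lx.enumerate_grid()
        assert len(grid) == 56
        assert sum(1 for c in grid if c.smote) == 28
        assert len({c.families for c in grid}) == 7

    def test_one_algorithm_is_14(self):
        grid = [c for c in lx.enumerate_grid() if c.algorithm == "random_forest"]
        assert len(grid) == 14

    def test_family_subsets_enumerated(self):
        assert len(lx.ml_harness.FAMILY_COMBINATIONS) == 2 ** 3 - 1


class TestCrossvalidate:
    def test_perfectly_separable_auc_one(self):
        labels = ["tox"] * 30 + ["nox"] * 30
        feature = ["A"] * 30 + ["X"] * 30
        noise = list(np.random.default_rng(0).choice(["X", "G"], 60))
        m = indicator_matrix([feature, noise], labels)
        rep = lx.crossvalidate(m, lx.ExperimentConfig(("AMP",), "tree_j48_like",
                                                      False, 5, 0))
        assert rep.auc == pytest.approx(1.0)

    def test_reproducible_given_seed(self, planted_matrix):
        cfg = lx.ExperimentConfig(("AMP",), "random_forest", False, 5, 3)
        r1 = lx.crossvalidate(planted_matrix, cfg)
        r2 = lx.crossvalidate(planted_matrix, cfg)
        assert r1.oof_scores == r2.oof_scores
        assert r1.confusion == r2.confusion

    def test_small_class_aborts_with_advice(self):
        m = indicator_matrix([["A"] * 12], ["tox"] * 3 + ["nox"] * 9)
        with pytest.raises(ValueError, match="fewer"):
            lx.crossvalidate(m, lx.ExperimentConfig(("AMP",), "logistic", False, 10, 0))

    def test_youden_j_in_range(self, planted_matrix):
        cfg = lx.ExperimentConfig(("AMP",), "bayes_net", False, 5, 0)
        rep = lx.crossvalidate(planted_matrix, cfg)
        thr, j, se, sp = rep.youden
        assert -1 <= j <= 1 and j == pytest.approx(se + sp - 1)


class TestSmote:
    def make_fold(self, n_tox=8, n_nox=20, seed=0):
        rng = np.random.default_rng(seed)
        labels = ["tox"] * n_tox + ["nox"] * n_nox
        cols = [list(rng.choice(["X", "A", "W"], len(labels))) for _ in range(6)]
        m = indicator_matrix(cols, labels)
        return m.data, m.labels

    def test_balanced_after_oversampling(self):
        X, y = self.make_fold()
        Xb, yb, _ = balance_training_fold(X, y, np.random.default_rng(0))
        assert (yb == "tox").sum() == (yb == "nox").sum()

    def test_synthetic_values_come_from_neighbour_vote(self):
        X, y = self.make_fold()
        minority = X[y == "tox"]
        synth, donors = lx.smote_nominal(minority, 10, np.random.default_rng(1), k=5)
        for row_i, donor_ids in zip(range(len(synth)), donors):
            neigh = minority.loc[donor_ids[1:]]
            for col in synth.columns:
                votes = neigh[col].value_counts()
                top = votes[votes == votes.max()].index.min()
                assert synth.iloc[row_i][col] == top

    def test_donors_never_include_test_fold(self, planted_matrix):
        donor_log = []
        cfg = lx.ExperimentConfig(("AMP",), "bayes_net", True, 5, 0)
        lx.crossvalidate(planted_matrix, cfg, _donor_log=donor_log)
        assert donor_log
        for entry in donor_log:
            used = {d for row in entry["donors"] for d in row}
            assert used <= set(entry["train_ids"])
            assert not used & set(entry["test_ids"])

    def test_already_balanced_fold_untouched(self):
        X, y = self.make_fold(n_tox=10, n_nox=10)
        Xb, yb, donors = balance_training_fold(X, y, np.random.default_rng(0))
        assert Xb.equals(X) and donors == []

    def test_too_few_minority_samples(self):
        X, y = self.make_fold(n_tox=1, n_nox=5)
        with pytest.raises(ValueError):
            lx.smote_nominal(X[y == "tox"], 3, np.random.default_rng(0))


class TestRandomLabelControl:
    def test_flip_count_and_determinism(self, planted_matrix):
        r1 = lx.random_label_control(planted_matrix, "tox", seed=5,
                                     algorithm="bayes_net", folds=5)
        r2 = lx.random_label_control(planted_matrix, "tox", seed=5,
                                     algorithm="bayes_net", folds=5)
        assert r1.oof_scores == r2.oof_scores
        n = (planted_matrix.labels == "tox").sum()
        tp, fp, tn, fn = r1.confusion
        assert tp + fp + tn + fn == n
        assert tp + fn == n - n // 2  # flipped fraction is exactly floor(n/2)

    def test_class_too_small(self, planted_matrix):
        with pytest.raises(ValueError):
            lx.random_label_control(planted_matrix, "tox", folds=200)


class TestIncrementalFeatures:
    def test_nested_trajectory(self, planted_matrix):
        ranked = lx.info_gain_rank(planted_matrix)
        reports = lx.incremental_feature_experiment(
            planted_matrix, ranked, k_per_family=3, algorithm="bayes_net", folds=5)
        assert len(reports) == min(3, len(ranked))
        # planted features enter early: final AUC clearly above chance
        assert reports[-1].auc > 0.7


class TestPredict:
    def test_germline_like_input_scores(self, planted_matrix, planted_dataset):
        cfg = lx.ExperimentConfig(("AMP",), "random_forest", False, 5, 0)
        model = lx.fit_model(planted_matrix, cfg, threshold=0.5)
        all_x = lx.SMutEncoding("gl_probe",
                                {p: "X" for p in planted_dataset["universe"]}, "g")
        m = lx.assemble_matrix([all_x], ("AMP",),
                               position_universe=planted_dataset["universe"])
        pred = lx.predict(model, m)
        assert 0.0 <= pred.loc["gl_probe", "confidence"] <= 1.0

    def test_prediction_deterministic(self, planted_matrix):
        cfg = lx.ExperimentConfig(("AMP",), "random_forest", False, 5, 0)
        model = lx.fit_model(planted_matrix, cfg, threshold=0.5)
        p1 = lx.predict(model, planted_matrix)
        p2 = lx.predict(model, planted_matrix)
        assert p1.equals(p2)

    def test_feature_universe_mismatch(self, planted_matrix):
        cfg = lx.ExperimentConfig(("AMP",), "logistic", False, 5, 0)
        model = lx.fit_model(planted_matrix, cfg, threshold=0.5)
        with pytest.raises(ValueError, match="universe"):
            model.score(planted_matrix.data.iloc[:, :3])

    def test_held_out_accuracy_on_strong_signal(self, toy_germlines):
        spec = lx.SimSpec(n_tox=120, n_nox=120, background_sm_rate=0.02, seed=21,
                          planted_effects=(lx.PlantedEffect(49, "A", 0.7, 0.02),
                                           lx.PlantedEffect(60, "W", 0.7, 0.02)))
        recs, _ = lx.generate_repertoire(spec)
        encs, scheme = lx.encode_dataset(recs, toy_germlines)
        labels = {r.sequence_id: r.label for r in recs}
        uni = sorted(set(scheme.values()))
        m = lx.assemble_matrix(encs, ("AMP",), labels=labels, position_universe=uni)
        train_ids = m.data.index[::2]
        test_ids = m.data.index[1::2]
        train = lx.FeatureMatrix(m.data.loc[train_ids], m.labels.loc[train_ids],
                                 m.descriptors)
        cfg = lx.ExperimentConfig(("AMP",), "random_forest", False, 5, 0)
        model = lx.fit_model(train, cfg, threshold=0.5)
        pred = lx.predict(model, lx.FeatureMatrix(m.data.loc[test_ids],
                                                  m.labels.loc[test_ids],
                                                  m.descriptors))
        acc = (pred["label"] == m.labels.loc[test_ids]).mean()
        assert acc > 0.8
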