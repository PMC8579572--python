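"""Feature construction, classifiers, evaluation metrics, LHS designs."""

import numpy as np
import pandas as pd
import pytest

from phylostruct import (FEATURE_COLUMNS, build_feature_matrix, classify_trees,
                         evaluate_predictions, kfold_cross_validate,
                         latin_hypercube_design, roc_auc, sensitivity_experiment,
                         statistics_table, tune_and_train, worked_example_tree)
from conftest import random_structured_tree, random_unstructured_tree


def concordance_auc(y, scores, positive="structured"):
    """Brute-force AUC oracle: fraction of concordant positive-negative
    pairs, ties counting one half."""
    y = np.asarray(y)
    pos = np.asarray(scores, dtype=float)[y == positive]
    neg = np.asarray(scores, dtype=float)[y != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def small_dataset_table():
    """Desk-scale baseline dataset: standard rates, shrunk tip counts."""
    from phylostruct import baseline_design, simulate_dataset
    design = baseline_design(7, n_unstructured=30, n_structured=30)
    design["n_tips_1"] = np.where(design.label == "non-structured", 70, 50)
    design.loc[design.label == "structured", "n_tips_2"] = 30
    return statistics_table(simulate_dataset(design).trees)


class TestFeatureMatrix:
    def test_shape_and_column_order(self, small_dataset_table):
        x, y = build_feature_matrix(small_dataset_table)
        assert x.shape == (60, 8)
        assert len(FEATURE_COLUMNS) == 8
        assert set(y) == {"structured", "non-structured"}

    def test_worked_example_feature_vector(self):
        tree = worked_example_tree()
        table = statistics_table([tree], labels=["structured"], tree_ids=["fx"])
        x, _ = build_feature_matrix(table)
        assert x[0] == pytest.approx([0.8, 1.0, 1 / 3, 6, 0.2, 4, 3, 4 / 3])

    def test_duplicate_ids_rejected(self, small_dataset_table):
        doubled = pd.concat([small_dataset_table, small_dataset_table])
        with pytest.raises(ValueError):
            build_feature_matrix(doubled)

    def test_missing_statistic_rejected(self, small_dataset_table):
        broken = small_dataset_table.copy()
        broken.loc[broken.index[0], "sackin_norm"] = np.nan
        with pytest.raises(ValueError):
            build_feature_matrix(broken)


class TestTuneAndTrain:
    def test_linear_svm_separates_separable_toy(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(5, 0.3, (20, 2))])
        y = np.array(["non-structured"] * 20 + ["structured"] * 20)
        fitted, _ = tune_and_train(x, y, "svm-linear")
        assert (fitted.predict(x) == y).all()

    def test_single_class_rejected(self):
        x = np.zeros((10, 2))
        with pytest.raises(ValueError):
            tune_and_train(x, np.repeat("structured", 10), "knn")

    def test_same_seed_same_hyperparameters(self, small_dataset_table):
        x, y = build_feature_matrix(small_dataset_table)
        _, p1 = tune_and_train(x, y, "knn", seed=4)
        _, p2 = tune_and_train(x, y, "knn", seed=4)
        assert p1 == p2

    def test_knn_grid_finds_accurate_model(self, small_dataset_table):
        x, y = build_feature_matrix(small_dataset_table)
        _, best = tune_and_train(x, y, "knn", seed=0)
        assert best["clf__n_neighbors"] in {3, 5, 7, 9, 11}
        ev = kfold_cross_validate(x, y, "knn", seed=0)
        assert ev.accuracy > 0.9


class TestCrossValidation:
    def test_perfect_separation(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.2, (30, 3)), rng.normal(4, 0.2, (30, 3))])
        y = np.array(["non-structured"] * 30 + ["structured"] * 30)
        ev = kfold_cross_validate(x, y, "svm-linear", seed=0)
        assert (ev.per_fold["accuracy"] == 1.0).all()
        assert ev.confusion.sum() == 60

    def test_label_permutation_null(self, small_dataset_table):
        """Random labels: mean AUC near one half, accuracy near chance."""
        x, y = build_feature_matrix(small_dataset_table)
        rng = np.random.default_rng(42)
        aucs, accs = [], []
        for rep in range(5):
            y_perm = rng.permutation(y)
            ev = kfold_cross_validate(x, y_perm, "knn", seed=rep, tune=False)
            aucs.append(ev.auc)
            accs.append(ev.accuracy)
        assert abs(np.mean(aucs) - 0.5) < 0.1
        assert abs(np.mean(accs) - 0.5) < 3 * np.std(accs, ddof=1) + 0.05

    def test_stratified_folds_preserve_class_ratio(self, small_dataset_table):
        from sklearn.model_selection import StratifiedKFold
        x, y = build_feature_matrix(small_dataset_table)
        for _, test_idx in StratifiedKFold(10, shuffle=True,
                                           random_state=0).split(x, y):
            n_pos = np.sum(y[test_idx] == "structured")
            assert abs(n_pos - len(test_idx) / 2) <= 1

    def test_deterministic_metrics(self, small_dataset_table):
        x, y = build_feature_matrix(small_dataset_table)
        e1 = kfold_cross_validate(x, y, "decision-tree", seed=3)
        e2 = kfold_cross_validate(x, y, "decision-tree", seed=3)
        assert e1.summary() == e2.summary()
        assert (e1.confusion == e2.confusion).all()


class TestEvaluation:
    def test_confusion_accuracy_example(self):
        y_true = np.array(["structured"] * 151 + ["non-structured"] * 156)
        y_pred = y_true.copy()
        y_pred[:1] = "non-structured"          # 1 false negative
        y_pred[-2:] = "structured"             # 2 false positives
        ev = evaluate_predictions(y_true, y_pred)
        assert ev.confusion.sum() == 307
        assert ev.accuracy == pytest.approx(304 / 307)
        assert ev.sensitivity == pytest.approx(150 / 151)
        assert ev.specificity == pytest.approx(154 / 156)

    def test_all_correct_and_all_positive(self):
        y = np.array(["structured", "non-structured"] * 5)
        perfect = evaluate_predictions(y, y)
        assert perfect.sensitivity == perfect.specificity == perfect.accuracy == 1.0
        allpos = evaluate_predictions(y, np.repeat("structured", 10))
        assert allpos.specificity == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_predictions(["structured"], ["structured"] * 2)


class TestRocAuc:
    def test_perfect_and_inverted_scores(self):
        y = np.array(["non-structured"] * 5 + ["structured"] * 5)
        s = np.arange(10.0)
        assert roc_auc(y, s)[0] == pytest.approx(1.0)
        assert roc_auc(y, -s)[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.choice(["structured", "non-structured"], size=30)
        if len(set(y)) < 2:
            y[0], y[1] = "structured", "non-structured"
        scores = rng.integers(0, 8, size=30).astype(float)  # forces ties
        auc, points = roc_auc(y, scores)
        assert auc == pytest.approx(concordance_auc(y, scores), abs=1e-12)
        assert points[0] == pytest.approx([0, 0])
        assert points[-1] == pytest.approx([1, 1])

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(8)
        y = np.repeat(["structured", "non-structured"], 500)
        auc, _ = roc_auc(y, rng.random(1000))
        assert abs(auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.repeat("structured", 4), np.arange(4.0))


class TestLatinHypercube:
    def test_one_sample_per_bin(self):
        design = latin_hypercube_design({"x": (0.0, 1.0)}, 10, rng=0)
        bins = np.floor(design.samples["x"].to_numpy() * 10).astype(int)
        assert sorted(bins) == list(range(10))

    def test_intervals_respected(self):
        intervals = {"r0_1": (0.45, 6.34), "r0_2": (4.18, 36.75)}
        design = latin_hypercube_design(intervals, 25, rng=1)
        for name, (lo, hi) in intervals.items():
            assert design.samples[name].between(lo, hi).all()

    def test_seeded_determinism(self):
        d1 = latin_hypercube_design({"x": (0, 1), "y": (2, 3)}, 8, rng=5)
        d2 = latin_hypercube_design({"x": (0, 1), "y": (2, 3)}, 8, rng=5)
        pd.testing.assert_frame_equal(d1.samples, d2.samples)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            latin_hypercube_design({"x": (1.0, 1.0)}, 5, rng=0)


@pytest.fixture(scope="module")
def fitted(small_dataset_table):
    x, y = build_feature_matrix(small_dataset_table)
    model, _ = tune_and_train(x, y, "svm-radial", seed=0)
    return model


class TestClassifyTrees:
    def test_self_consistency_on_heldout_structured(self, fitted):
        from phylostruct import DemeParameters, SimulationConfig, \
            simulate_structured_tree
        params = (DemeParameters(3.0639, 0.014, 0.3),
                  DemeParameters(4.0178, 0.042, 0.2))
        held_out = [simulate_structured_tree(
            params, SimulationConfig(n_tips=(50, 30)),
            np.random.default_rng(500 + s)) for s in range(20)]
        report = classify_trees(fitted, held_out)
        frac = (report["predicted"] == "structured").mean()
        assert frac >= 0.9

    def test_empty_tree_set(self, fitted):
        report = classify_trees(fitted, [])
        assert report.empty
        assert report.attrs["proportions"] == {}

    def test_proportions_sum_to_hundred(self, fitted):
        trees = [random_unstructured_tree(900 + s, n_tips=40) for s in range(8)]
        report = classify_trees(fitted, trees)
        assert sum(report.attrs["proportions"].values()) == pytest.approx(100.0)


class TestSensitivityExperiment:
    def test_desk_scale_experiment(self):
        """Tiny LHS-varied datasets: the report has one row per mode/model
        and varied-size keeps baseline rates."""
        report = sensitivity_experiment(
            modes=("varied-size",), models=("decision-tree",), seed=1,
            n_unstructured=12, n_structured=12, k_folds=4,
            design_kwargs={"size_intervals": ((30, 40), (25, 30)),
                           "unstructured_size_interval": (30, 40)})
        assert list(report["mode"]) == ["varied-size"]
        assert report["n_trees"].iloc[0] == 24
        assert 0.0 <= report["accuracy"].iloc[0] <= 1.0

    def test_varied_size_keeps_baseline_rates(self):
        from phylostruct import baseline_design, varied_design
        base = baseline_design(2, 5, 5)
        varied = varied_design(2, "varied-size", 5, 5,
                               size_intervals=((30, 40), (25, 30)),
                               unstructured_size_interval=(30, 40))
        rate_cols = ["lambda_1", "mu_1", "alpha_12", "lambda_2", "mu_2", "alpha_21"]
        pd.testing.assert_frame_equal(base[rate_cols], varied[rate_cols])
        assert varied.loc[varied.label == "structured", "n_tips_2"].between(25, 30).all()
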