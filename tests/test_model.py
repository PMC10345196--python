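import numpy as np
import pandas as pd
import pytest

import funcsites as fs
from funcsites.model import DEFAULT_PARAMS, VariantClassifierModel, evaluate


def small_model(balanced_features, seed=0, **kwargs):
    X, y = balanced_features
    return VariantClassifierModel(X, y, seed=seed, **kwargs)


class TestStratifiedFolds:
    def test_balanced_exact_divisibility(self):
        X = pd.DataFrame(np.zeros((100, 8)), columns=fs.FEATURE_NAMES)
        y = (["WT_like"] * 25 + ["total_loss"] * 25 + ["SBI"] * 25
             + ["low_abundance_high_activity"] * 25)
        model = VariantClassifierModel(X, y, seed=1)
        for _, val in model.stratified_folds(5):
            assert len(val) == 20
            counts = pd.Series(np.asarray(y, dtype=object)[val]).value_counts()
            assert (counts == 5).all()

    def test_partition_property(self):
        X = pd.DataFrame(np.zeros((97, 8)), columns=fs.FEATURE_NAMES)
        y = (["WT_like"] * 40 + ["total_loss"] * 30 + ["SBI"] * 17
             + ["low_abundance_high_activity"] * 10)
        model = VariantClassifierModel(X, y, seed=2)
        folds = model.stratified_folds(5)
        all_val = np.concatenate([val for _, val in folds])
        assert sorted(all_val.tolist()) == list(range(97))
        for i, (_, a) in enumerate(folds):
            for _, b in folds[i + 1:]:
                assert not set(a) & set(b)

    def test_imbalanced_within_one_of_proportional(self):
        X = pd.DataFrame(np.zeros((100, 8)), columns=fs.FEATURE_NAMES)
        y = (["WT_like"] * 70 + ["total_loss"] * 10 + ["SBI"] * 10
             + ["low_abundance_high_activity"] * 10)
        model = VariantClassifierModel(X, y, seed=3)
        for _, val in model.stratified_folds(5):
            counts = pd.Series(np.asarray(y, dtype=object)[val]).value_counts()
            assert abs(counts["WT_like"] - 14) <= 1
            for cls in ("total_loss", "SBI", "low_abundance_high_activity"):
                assert abs(counts[cls] - 2) <= 1

    def test_rare_class_error(self):
        X = pd.DataFrame(np.zeros((20, 8)), columns=fs.FEATURE_NAMES)
        y = ["WT_like"] * 17 + ["SBI"] * 3
        with pytest.raises(ValueError, match="fewer than k"):
            VariantClassifierModel(X, y, seed=0).stratified_folds(5)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = ["WT_like", "SBI", "total_loss", "low_abundance_high_activity"] * 3
        rep = evaluate(y, y)
        assert rep["accuracy"] == 1.0
        assert rep["mcc"] == 1.0

    def test_constant_prediction_on_balanced_truth(self):
        y = ["WT_like", "SBI", "total_loss", "low_abundance_high_activity"] * 25
        pred = ["WT_like"] * 100
        rep = evaluate(y, pred)
        assert rep["accuracy"] == pytest.approx(0.25)
        assert rep["mcc"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_confusion_matrix(self):
        truth = ["WT_like"] * 5 + ["SBI"] * 4 + ["total_loss"] * 3
        pred = (["WT_like"] * 4 + ["SBI"]          # 4/5 WT correct
                + ["SBI"] * 2 + ["total_loss"] * 2  # 2/4 SBI correct
                + ["total_loss"] * 3)               # 3/3 TL correct
        rep = evaluate(truth, pred)
        assert rep["accuracy"] == pytest.approx(9 / 12)
        cm = rep["confusion_matrix"]
        assert cm.loc["WT_like", "WT_like"] == 4
        assert cm.loc["WT_like", "SBI"] == 1
        assert cm.loc["SBI", "total_loss"] == 2
        assert rep["recall"]["SBI"] == pytest.approx(0.5)
        assert rep["precision"]["total_loss"] == pytest.approx(3 / 5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(["SBI"], ["SBI", "SBI"])


class TestFitAndPredict:
    def test_planted_clusters_high_cv_accuracy(self, balanced_features):
        model = small_model(balanced_features, seed=4)
        results = model.fit(n_estimators=150)
        assert results.cv_summary()["mean_cv_accuracy"] >= 0.95

    def test_deterministic_rerun_bit_identical(self, balanced_features):
        X, y = balanced_features
        p = []
        for _ in range(2):
            res = VariantClassifierModel(X, y, seed=9).fit(
                n_estimators=80, cross_validate=False
            )
            p.append(res.predict(X).filter(like="prob_").to_numpy())
        assert (p[0] == p[1]).all()

    def test_probabilities_sum_to_one(self, balanced_features):
        model = small_model(balanced_features, seed=4)
        res = model.fit(n_estimators=50, cross_validate=False)
        probs = res.predict(model.features).filter(like="prob_").to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_argmax_matches_predicted_class(self, balanced_features):
        model = small_model(balanced_features, seed=4)
        res = model.fit(n_estimators=50, cross_validate=False)
        pred = res.predict(model.features)
        probs = pred.filter(like="prob_").to_numpy()
        classes = [c.removeprefix("prob_") for c in pred.filter(like="prob_")]
        argmax = [classes[i] for i in probs.argmax(axis=1)]
        assert (pred["predicted_class"] == argmax).all()

    def test_row_permutation_permutes_outputs(self, balanced_features):
        model = small_model(balanced_features, seed=4)
        res = model.fit(n_estimators=50, cross_validate=False)
        perm = np.random.default_rng(0).permutation(len(model.features))
        direct = res.predict(model.features).iloc[perm].reset_index(drop=True)
        shuffled = res.predict(model.features.iloc[perm].reset_index(drop=True))
        pd.testing.assert_frame_equal(direct, shuffled)

    def test_missing_feature_column_error(self, balanced_features):
        model = small_model(balanced_features, seed=4)
        res = model.fit(n_estimators=10, cross_validate=False)
        with pytest.raises(ValueError, match="wcn"):
            res.predict(model.features.drop(columns=["wcn"]))

    def test_incomplete_rows_unpredicted(self, balanced_features):
        model = small_model(balanced_features, seed=4)
        res = model.fit(n_estimators=10, cross_validate=False)
        X = model.features.copy()
        X.loc[0, "ddG_variant"] = np.nan
        pred = res.predict(X)
        assert pred.loc[0, "predicted_class"] == "unpredicted"
        assert (pred.loc[1:, "predicted_class"] != "unpredicted").all()

    def test_nan_features_rejected_at_construction(self):
        X = pd.DataFrame(np.zeros((20, 8)), columns=fs.FEATURE_NAMES)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            VariantClassifierModel(X, ["SBI"] * 20)

    def test_save_load_round_trip(self, balanced_features, tmp_path):
        model = small_model(balanced_features, seed=4)
        res = model.fit(n_estimators=40, cross_validate=False)
        path = tmp_path / "model.joblib"
        res.save(path)
        loaded = fs.VariantClassifierResults.load(path)
        a = res.predict(model.features).filter(like="prob_").to_numpy()
        b = loaded.predict(model.features).filter(like="prob_").to_numpy()
        assert (a == b).all()

    def test_summary_mentions_features_and_cv(self, balanced_features):
        model = small_model(balanced_features, seed=4)
        res = model.fit(n_estimators=40, k=3)
        text = res.summary()
        assert "CV accuracy" in text and "wcn" in text


class TestGridSearch:
    def test_grid_of_one_equals_plain_fit(self, balanced_features):
        model = small_model(balanced_features, seed=6)
        grid = {k: [v] for k, v in DEFAULT_PARAMS.items()}
        via_grid = model.grid_search(grid=grid, k=3, n_estimators=60)
        plain = model.fit(params=DEFAULT_PARAMS, n_estimators=60, k=3)
        assert via_grid.params == plain.params
        assert via_grid.cv_summary() == plain.cv_summary()
        a = via_grid.predict(model.features).filter(like="prob_").to_numpy()
        b = plain.predict(model.features).filter(like="prob_").to_numpy()
        assert (a == b).all()

    def test_seeded_rerun_selects_same_hyperparameters(self, balanced_features):
        X, y = balanced_features
        grid = {"max_depth": [4, 6], "learning_rate": [0.1, 0.3]}
        runs = [
            VariantClassifierModel(X, y, seed=7).grid_search(
                grid=grid, k=3, n_estimators=40
            )
            for _ in range(2)
        ]
        assert runs[0].params == runs[1].params
        assert runs[0].cv_summary() == runs[1].cv_summary()

    def test_scan_logged_for_every_combination(self, balanced_features):
        model = small_model(balanced_features, seed=6)
        grid = {"max_depth": [4, 6], "reg_lambda": [1.0, 10.0]}
        res = model.grid_search(grid=grid, k=3, n_estimators=30)
        assert len(res.grid_scan) == 4
        assert "mean_cv_accuracy" in res.grid_scan.columns

    def test_empty_grid_error(self, balanced_features):
        model = small_model(balanced_features, seed=6)
        with pytest.raises(ValueError, match="empty"):
            model.grid_search(grid={"max_depth": []})


class TestBaselines:
    def test_null_model_predicts_modal_class(self, balanced_features):
        X, _ = balanced_features
        y = (["WT_like"] * 720 + ["total_loss"] * 200 + ["SBI"] * 180
             + ["low_abundance_high_activity"] * 100)
        model = VariantClassifierModel(X, y, seed=8)
        null = model.null_model()
        pred = null.predict(X)
        assert (pred["predicted_class"] == "WT_like").all()
        assert null.evaluate(X, y)["accuracy"] == pytest.approx(0.6)

    def test_null_model_tie_breaks_lexicographically(self):
        X = pd.DataFrame(np.zeros((20, 8)), columns=fs.FEATURE_NAMES)
        y = ["WT_like"] * 10 + ["SBI"] * 10
        null = VariantClassifierModel(X, y, seed=0).null_model()
        # 'SBI' < 'WT_like' lexicographically
        assert (null.predict(X)["predicted_class"] == "SBI").all()

    def test_null_below_tuned_model_on_separable_data(self, balanced_features):
        model = small_model(balanced_features, seed=4)
        tuned = model.fit(n_estimators=80)
        null = model.null_model()
        assert (null.cv_summary()["mean_cv_accuracy"]
                < tuned.cv_summary()["mean_cv_accuracy"])

    def test_random_forest_report_schema_matches(self, balanced_features):
        model = small_model(balanced_features, seed=4)
        rf = model.random_forest(params={"n_estimators": 50}, k=3)
        boosted = model.fit(n_estimators=40, k=3)
        assert set(rf.cv_report[0]) == set(boosted.cv_report[0])
        assert rf.cv_summary()["mean_cv_accuracy"] > 0.9


class TestFeatureImportanceSanity:
    def test_permuting_informative_feature_degrades_accuracy(self):
        # class identity carried jointly and non-redundantly by the two
        # variant scores; every other column is pure noise
        rng = np.random.default_rng(13)
        centers = {
            "WT_like": (0.5, -0.5),
            "total_loss": (4.0, -5.0),
            "SBI": (0.5, -5.0),
            "low_abundance_high_activity": (4.0, -0.5),
        }
        X = pd.DataFrame(
            rng.normal(size=(1200, 8)), columns=fs.FEATURE_NAMES
        )
        y = [cls for cls in centers for _ in range(300)]
        for i, cls in enumerate(centers):
            rows = X.index[300 * i:300 * (i + 1)]
            X.loc[rows, "ddG_variant"] = rng.normal(centers[cls][0], 0.3, 300)
            X.loc[rows, "ddE_variant"] = rng.normal(centers[cls][1], 0.4, 300)
        model = VariantClassifierModel(X, y, seed=13)
        res = model.fit(n_estimators=100, cross_validate=False)
        base_acc = evaluate(y, res.predict(X)["predicted_class"])["accuracy"]

        def permuted_accuracy(column):
            Xp = X.copy()
            Xp[column] = rng.permutation(Xp[column].to_numpy())
            return evaluate(y, res.predict(Xp)["predicted_class"])["accuracy"]

        assert base_acc - permuted_accuracy("ddG_variant") > 0.1
        assert base_acc - permuted_accuracy("hydrophobicity_target") < 0.02
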