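"""Classification protocol: splits, RFE, tuning, metrics, importance."""

import numpy as np
import pandas as pd
import pytest

from speechmarker.classify import (
    ClassificationProtocol,
    aggregate_report,
    auc_score,
    build_predictor_sets,
    evaluate,
    importance,
    make_splits,
    rfe_select,
    tune_and_train,
)

FAST = ClassificationProtocol(
    rfe_cv_folds=5, rfe_cv_repeats=1, tune_cv_folds=5, tune_cv_repeats=2,
    grid_points=5, rf_n_estimators=60, n_permutations=5,
)


def brute_force_auc(y, s):
    """Independent oracle: concordant pairs, ties half, over all pos/neg pairs."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _planted(rng, n=100, p=5, delta=1.5):
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"x{i}" for i in range(p)])
    X["x0"] = X["x0"] + y * delta
    return X, y


class TestPredictorSets:
    def test_covariates_in_every_set(self):
        sets = build_predictor_sets()
        for cols in sets.values():
            assert "age" in cols and "education" in cols
        assert len(sets["linguistic"]) == 17
        assert set(sets["biomarkers"]) == {"suvr", "hippocampus_cm3", "age", "education"}
        assert set(sets["combined"]) == set(sets["linguistic"]) | set(sets["biomarkers"])


class TestMakeSplits:
    def test_exact_stratification_when_divisible(self):
        y = np.repeat([0, 1], 10)
        for train, test in make_splits(y, n_repeats=5, train_fraction=0.7, seed=0):
            assert (y[train] == 0).sum() == 7 and (y[train] == 1).sum() == 7
            assert (y[test] == 0).sum() == 3 and (y[test] == 1).sum() == 3

    def test_unbalanced_cohort_proportions(self):
        y = np.array([0] * 32 + [1] * 48)
        for train, test in make_splits(y, n_repeats=3, seed=1):
            assert len(train) + len(test) == 80
            assert set(train) | set(test) == set(range(80))
            assert not set(train) & set(test)
            # stratified allocation up to rounding
            assert abs((y[train] == 0).sum() - 22.4) <= 1
            assert abs((y[train] == 1).sum() - 33.6) <= 1

    def test_deterministic_under_seed(self):
        y = np.repeat([0, 1], 20)
        a = make_splits(y, seed=5)
        b = make_splits(y, seed=5)
        assert all((np.array_equal(t1, t2) and np.array_equal(e1, e2))
                   for (t1, e1), (t2, e2) in zip(a, b))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            make_splits(np.array([0] * 3 + [1] * 20))


class TestAucScore:
    def test_perfect_separation(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_half(self):
        assert auc_score([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_partial_concordance(self):
        assert auc_score([0, 0, 1, 1], [0.6, 0.2, 0.8, 0.4]) == 0.75

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        y = rng.integers(0, 2, n)
        s = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], n)  # deliberate ties
        expected = brute_force_auc(y, s)
        got = auc_score(y, s)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


class TestEvaluate:
    def test_threshold_metrics_on_clean_scores(self):
        class Stub:
            selected = ["x"]

            def predict_score(self, X):
                return np.array([0.1, 0.2, 0.8, 0.9])

        out = evaluate(Stub(), pd.DataFrame({"x": [0, 0, 0, 0]}), [0, 0, 1, 1])
        assert out == {"AUC": 1.0, "specificity": 1.0, "precision": 1.0,
                       "recall": 1.0, "F1": 1.0}

    def test_single_class_test_set_auc_missing(self):
        class Stub:
            selected = ["x"]

            def predict_score(self, X):
                return np.array([0.6, 0.7])

        out = evaluate(Stub(), pd.DataFrame({"x": [0, 0]}), [1, 1])
        assert np.isnan(out["AUC"])


class TestRfeSelect:
    def test_single_predictor_returned(self):
        rng = np.random.default_rng(0)
        X, y = _planted(rng, p=1)
        assert rfe_select(X, y, "rf", FAST, seed=0) == ["x0"]

    def test_separating_predictor_survives(self):
        rng = np.random.default_rng(1)
        X, y = _planted(rng, n=100, p=6, delta=2.0)
        sel = rfe_select(X, y, "rf", FAST, seed=2)
        assert "x0" in sel

    def test_duplicated_separator_never_empty(self):
        rng = np.random.default_rng(3)
        X, y = _planted(rng, n=80, p=2, delta=2.5)
        X["x1"] = X["x0"]
        sel = rfe_select(X, y, "rf", FAST, seed=3)
        assert 1 <= len(sel) <= 2

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.5]})
        with pytest.raises(ValueError):
            rfe_select(X, np.zeros(3), "rf", FAST, seed=0)


class TestTuneAndTrain:
    def test_separable_data_train_auc_one(self):
        rng = np.random.default_rng(5)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame({"x0": rng.standard_normal(n) * 0.1 + y * 10.0})
        model = tune_and_train(X, y, ["x0"], "svm", FAST, seed=0)
        assert auc_score(y, model.predict_score(X)) == 1.0

    def test_knn_choice_is_grid_member(self):
        rng = np.random.default_rng(6)
        X, y = _planted(rng, n=80, p=3)
        model = tune_and_train(X, y, list(X.columns), "knn", FAST, seed=1)
        assert model.best_params["model__n_neighbors"] in range(5, 24, 2)

    def test_same_seed_same_hyperparameters(self):
        rng = np.random.default_rng(7)
        X, y = _planted(rng, n=80, p=3)
        m1 = tune_and_train(X, y, list(X.columns), "rf", FAST, seed=9)
        m2 = tune_and_train(X, y, list(X.columns), "rf", FAST, seed=9)
        assert m1.best_params == m2.best_params

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            tune_and_train(pd.DataFrame({"x": [1.0, 2.0]}), [0, 1], [], "svm", FAST)


class TestImportance:
    def test_single_feature_scores_100(self):
        rng = np.random.default_rng(8)
        X, y = _planted(rng, n=60, p=1)
        model = tune_and_train(X, y, ["x0"], "rf", FAST, seed=0)
        imp = importance(model, X, y, FAST, seed=0)
        assert imp["x0"] == pytest.approx(100.0)

    @pytest.mark.parametrize("model_name", ["rf", "svm", "knn"])
    def test_informative_feature_outranks_noise(self, model_name):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, y = _planted(rng, n=100, p=2, delta=2.0)
            model = tune_and_train(X, y, ["x0", "x1"], model_name, FAST, seed=seed)
            imp = importance(model, X, y, FAST, seed=seed)
            hits += imp["x0"] > imp["x1"]
        assert hits >= 9

    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(9)
        X, y = _planted(rng, n=60, p=2)
        model = tune_and_train(X, y, ["x0", "x1"], "knn", FAST, seed=0)
        proto = ClassificationProtocol(n_permutations=0)
        with pytest.raises(ValueError):
            importance(model, X, y, proto, seed=0)


class TestCohortOrdering:
    def test_combined_predictors_not_worse_than_linguistic_alone(self):
        """Adding biomarkers to the linguistic set never costs AUC (beyond
        noise) on the default synthetic cohort."""
        import speechmarker as sm
        from speechmarker.classify import run_classification
        from speechmarker.synthetic import default_config, generate_cohort

        cohort = generate_cohort(default_config(seed=13))
        feats = pd.DataFrame(
            [sm.extract_features(t, cohort.lexicon) for t in cohort.transcripts],
            index=[t.participant_id for t in cohort.transcripts],
        )
        frame = cohort.frame().set_index("participant_id").join(feats).reset_index()
        sets = {k: v for k, v in build_predictor_sets().items() if k != "biomarkers"}
        protocol = ClassificationProtocol(
            n_repeats=3, rfe_cv_folds=3, rfe_cv_repeats=1, tune_cv_folds=3,
            tune_cv_repeats=1, grid_points=3, rf_n_estimators=50, n_permutations=3,
        )
        report = run_classification(frame, sets, models=("rf",), protocol=protocol, seed=13)
        auc = report.metrics.set_index("predictor_set")["AUC"]
        assert auc["combined"] >= auc["linguistic"] - 0.02


class TestAggregateReport:
    def _record(self, repeat, selected, imps, auc=0.9):
        return {"predictor_set": "linguistic", "model": "svm", "repeat": repeat,
                "selected": selected, "importance": imps,
                "AUC": auc, "specificity": 0.8, "precision": 0.8,
                "recall": 0.8, "F1": 0.8}

    def test_selection_frequency_and_mean_importance(self):
        recs = [self._record(0, ["LPR"], {"LPR": 80.0}),
                self._record(1, ["LPR"], {"LPR": 100.0})]
        rep = aggregate_report(recs, n_repeats=2)
        row = rep.importance.iloc[0]
        assert row["feature"] == "LPR"
        assert row["mean_importance"] == pytest.approx(90.0)
        assert row["selection_pct"] == pytest.approx(100.0)

    def test_never_selected_feature_absent(self):
        recs = [self._record(0, ["LPR"], {"LPR": 80.0, "MLU": 40.0})]
        rep = aggregate_report(recs, n_repeats=1)
        assert "MLU" not in set(rep.importance["feature"])

    def test_empty_runs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])
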