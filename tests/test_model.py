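"""Cross-validation discipline, grid search, RFE, and ensembles."""

import numpy as np
import pandas as pd
import pytest

from evmap.model import (
    ConstantScore,
    CVSpec,
    EnsembleModel,
    HyperGrid,
    OptimizedClassifier,
    benchmark,
    default_learners,
    grid_search,
    make_folds,
    make_repeated_folds,
    repeated_cv,
    rfe,
    train_ensemble,
    xgb_classifier,
)


def planted_data(rng, n=80, p=30, informative=(0,), shift=2.0):
    X = rng.normal(size=(n, p))
    y = np.repeat([0, 1], n // 2)
    for c in informative:
        X[y == 1, c] += shift
    perm = rng.permutation(n)
    return X[perm], y[perm]


FAST = {"nrounds": 30, "max_depth": 3, "eta": 0.3}


class TestFolds:
    def test_215_patients_split_into_five_folds_of_43(self, rng):
        y = (rng.random(215) < 0.15).astype(int)
        folds = make_folds(y, 5, seed=0)
        assert sorted(len(f) for f in folds) == [43] * 5

    def test_every_patient_validated_once_per_repeat(self, rng):
        y = (rng.random(57) < 0.3).astype(int)
        spec = CVSpec(folds=5, repeats=4, base_seed=9)
        for val_folds in make_repeated_folds(y, spec):
            seen = np.concatenate(val_folds)
            assert sorted(seen) == list(range(57))

    def test_training_folds_always_contain_both_classes(self, rng):
        y = np.zeros(40, dtype=int)
        y[:3] = 1  # rare positives
        folds = make_folds(y, 5, seed=1)
        for f, val in enumerate(folds):
            train = np.concatenate([v for g, v in enumerate(folds) if g != f])
            assert len(np.unique(y[train])) == 2


class TestRepeatedCV:
    def test_constant_learner_scores_half(self, rng):
        X, y = planted_data(rng)
        res = repeated_cv(X, y, ConstantScore(0.5), CVSpec(repeats=3))
        np.testing.assert_allclose(res.aucs, 0.5)

    def test_deterministic_given_seed(self, rng):
        X, y = planted_data(rng, n=40, p=10)
        spec = CVSpec(repeats=2, base_seed=5)
        r1 = repeated_cv(X, y, xgb_classifier(FAST), spec)
        r2 = repeated_cv(X, y, xgb_classifier(FAST), spec)
        np.testing.assert_array_equal(r1.oof, r2.oof)
        np.testing.assert_array_equal(r1.aucs, r2.aucs)

    def test_held_out_label_cannot_influence_own_score(self, rng):
        """Corrupting one held-out label never changes that patient's score."""
        X, y = planted_data(rng, n=40, p=10)
        spec = CVSpec(folds=4, repeats=1, base_seed=2)
        folds = make_repeated_folds(y, spec)
        target = folds[0][0][0]  # a patient validated in fold 0
        r1 = repeated_cv(X, y, xgb_classifier(FAST), spec, folds=folds)
        y_poisoned = y.copy()
        y_poisoned[target] = 1 - y_poisoned[target]
        r2 = repeated_cv(X, y_poisoned, xgb_classifier(FAST), spec, folds=folds)
        assert r1.oof[0, target] == r2.oof[0, target]

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            repeated_cv(X, np.zeros(20, dtype=int), ConstantScore(), CVSpec())


class TestBenchmark:
    def test_boosted_trees_beat_random_guess_on_planted_cohort(self, rng):
        X, y = planted_data(rng, n=100, p=20)
        learners = {"boosted": xgb_classifier(FAST), "guess": ConstantScore(0.5)}
        table = benchmark(X, y, learners, CVSpec(repeats=2))
        by = table.set_index("learner")["mean_auc"]
        assert by["boosted"] > by["guess"]

    def test_duplicated_learners_get_identical_results(self, rng):
        X, y = planted_data(rng, n=60, p=10)
        learners = {"a": xgb_classifier(FAST), "b": xgb_classifier(FAST)}
        table = benchmark(X, y, learners, CVSpec(repeats=2)).set_index("learner")
        assert table.loc["a", "mean_auc"] == table.loc["b", "mean_auc"]

    def test_failing_learner_recorded_not_fatal(self, rng):
        class Broken:
            def get_params(self, deep=True):
                return {}

            def fit(self, X, y):
                raise RuntimeError("boom")

        X, y = planted_data(rng, n=40, p=5)
        table = benchmark(
            X, y, {"ok": ConstantScore(), "broken": Broken()}, CVSpec(repeats=1)
        ).set_index("learner")
        assert np.isnan(table.loc["broken", "mean_auc"])
        assert table.loc["ok", "mean_auc"] == 0.5

    def test_default_learner_panel_has_four_baselines(self):
        assert set(default_learners()) == {
            "boosted_trees", "bagged_trees", "penalized_logistic", "knn"
        }

    def test_fewer_than_two_learners_rejected(self, rng):
        X, y = planted_data(rng, n=20, p=3)
        with pytest.raises(ValueError):
            benchmark(X, y, {"only": ConstantScore()}, CVSpec(repeats=1))


class TestGridSearch:
    def test_printed_grid_enumerates_56_combinations(self):
        assert len(HyperGrid()) == 7 * 4 * 2 == 56

    def test_singleton_grid_returned(self, rng):
        X, y = planted_data(rng, n=40, p=5)
        grid = HyperGrid(nrounds=(30,), max_depth=(3,), eta=(0.3,))
        best, table = grid_search(X, y, grid, CVSpec(repeats=1))
        assert len(table) == 1
        assert best["nrounds"] == 30 and best["max_depth"] == 3

    def test_equal_auc_tie_broken_by_fewer_rounds(self, rng):
        # perfectly separable -> every combination reaches AUC 1
        X = np.zeros((40, 2))
        y = np.repeat([0, 1], 20)
        X[:, 0] = y * 10.0
        grid = HyperGrid(nrounds=(50, 100), max_depth=(4, 3), eta=(0.3,))
        best, table = grid_search(X, y, grid, CVSpec(repeats=1))
        assert table["mean_auc"].nunique() == 1
        assert best["nrounds"] == 50
        assert best["max_depth"] == 3

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid(nrounds=())


class TestRFE:
    def test_informative_column_survives_among_noise(self, rng):
        X, y = planted_data(rng, n=80, p=51, informative=(7,), shift=2.5)
        selected, profile = rfe(X, y, CVSpec(repeats=1, base_seed=3),
                                min_features=2)
        assert 7 in selected

    def test_profile_has_one_row_per_subset_size(self, rng):
        X, y = planted_data(rng, n=40, p=16)
        _, profile = rfe(X, y, CVSpec(repeats=1), drop_fraction=0.5,
                         min_features=2)
        assert profile["n_features"].tolist() == [16, 8, 4, 2]

    def test_identical_columns_keep_auc_unchanged(self, rng):
        X = np.tile(rng.normal(size=(30, 1)), (1, 6))
        y = np.repeat([0, 1], 15)
        selected, profile = rfe(X, y, CVSpec(repeats=1), min_features=1)
        assert len(selected) >= 1
        assert profile["mean_auc"].nunique() == 1

    def test_single_column_rejected(self, rng):
        with pytest.raises(ValueError):
            rfe(rng.normal(size=(20, 1)), np.repeat([0, 1], 10), CVSpec())


class _StubBooster:
    """Minimal member that predicts a fixed probability."""

    def __init__(self, p):
        self.p = p

    def inplace_predict(self, X):
        return np.full(np.asarray(X).shape[0], self.p, dtype=np.float32)


class TestEnsemble:
    def test_single_member_full_fraction_equals_plain_model(self, rng):
        X, y = planted_data(rng, n=40, p=8)
        ens = train_ensemble(X, y, n_members=1, params=FAST,
                             subsample_fraction=1.0, base_seed=4)
        plain = xgb_classifier(FAST, seed=4).fit(X, y)
        np.testing.assert_allclose(
            ens.predict(X), plain.predict_proba(X)[:, 1], atol=1e-7
        )

    def test_prediction_is_mean_of_member_probabilities(self):
        ens = EnsembleModel(
            members=[_StubBooster(0.2), _StubBooster(0.4), _StubBooster(0.6)],
            member_seeds=[0, 1, 2],
            subsample_fraction=1.0,
        )
        np.testing.assert_allclose(ens.predict(np.zeros((5, 2))), 0.4, atol=1e-7)

    def test_row_permutation_permutes_predictions(self, rng):
        X, y = planted_data(rng, n=40, p=8)
        ens = train_ensemble(X, y, n_members=3, params=FAST, base_seed=0)
        perm = rng.permutation(40)
        np.testing.assert_array_equal(ens.predict(X)[perm], ens.predict(X[perm]))

    def test_serialization_round_trip_bit_identical(self, rng, tmp_path):
        X, y = planted_data(rng, n=40, p=8)
        ens = train_ensemble(X, y, n_members=4, params=FAST, base_seed=1,
                             selected_features=np.array([0, 2, 5, 7]))
        ens.save(tmp_path / "model")
        back = EnsembleModel.load(tmp_path / "model")
        np.testing.assert_array_equal(ens.predict(X), back.predict(X))
        np.testing.assert_array_equal(back.selected_features, [0, 2, 5, 7])

    def test_feature_matrix_mismatch_names_missing_columns(self, rng):
        from evmap.binning import FeatureMatrix

        X, y = planted_data(rng, n=20, p=4)
        fm = FeatureMatrix(
            patients=[f"p{i}" for i in range(20)],
            values=np.abs(X),
            columns=[(("a", "b"), 0, j) for j in range(4)],
        )
        ens = train_ensemble(fm, y, n_members=1, params=FAST)
        other = FeatureMatrix(
            patients=fm.patients,
            values=np.abs(X),
            columns=[(("a", "b"), 1, j) for j in range(4)],
        )
        with pytest.raises(ValueError, match="frozen binning"):
            ens.predict(other)

    def test_invalid_member_count_rejected(self, rng):
        X, y = planted_data(rng, n=20, p=4)
        with pytest.raises(ValueError):
            train_ensemble(X, y, n_members=0)


class TestOptimizedClassifier:
    def test_nested_pipeline_learns_planted_signal(self, rng):
        X, y = planted_data(rng, n=60, p=24, informative=(3, 11), shift=2.5)
        clf = OptimizedClassifier(
            grid=None, do_rfe=True, rfe_min_features=4, n_members=4,
            params=FAST, random_state=0,
        )
        res = repeated_cv(X, y, clf, CVSpec(folds=3, repeats=1, base_seed=1))
        assert res.mean_auc > 0.8

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = OptimizedClassifier(n_members=7, params=FAST)
        assert clone(clf).n_members == 7
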