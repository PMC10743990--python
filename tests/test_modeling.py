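import numpy as np
import pytest

import consensusvs as cvs
from consensusvs.curation import LabeledDataset
from consensusvs.modeling import (
    ModelSpec,
    ModelingError,
    TanimotoKernelSVC,
    build_estimator,
    default_grid,
    evaluate,
    grid_search,
    repeated_split_cv,
    train,
    y_randomization,
)


class TestDefaultGrids:
    @pytest.mark.parametrize(
        "algorithm,n_combos",
        [("RF", 6), ("SVM", 10), ("KNN", 60), ("MLP", 144)],
    )
    def test_grid_sizes_match_printed_lists(self, algorithm, n_combos):
        assert len(default_grid(algorithm).combinations()) == n_combos

    def test_unknown_algorithm(self):
        with pytest.raises(ModelingError):
            default_grid("GBM")


class TestEvaluate:
    def test_formula_arithmetic(self):
        pred = [1] * 3 + [1] + [0] * 2 + [0] * 2
        true = [1] * 3 + [0] + [0] * 2 + [1] * 2
        rep = evaluate(pred, true)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (3, 2, 1, 2)
        assert rep.accuracy == pytest.approx(0.625)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)

    def test_perfect_predictions(self):
        rep = evaluate([1, 0, 1], [1, 0, 1])
        assert rep.accuracy == rep.precision == rep.recall == 1.0

    def test_degenerate_denominators_warn_and_zero(self):
        with pytest.warns(UserWarning):
            rep = evaluate([0, 0], [1, 0])
        assert rep.precision == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ModelingError):
            evaluate([1], [1, 0])

    def test_string_labels_accepted(self):
        rep = evaluate(["active", "inactive"], ["active", "active"])
        assert (rep.tp, rep.fn) == (1, 1)

    def test_against_brute_force_oracle(self, rng):
        def brute(pred, true):
            tp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 1)
            tn = sum(1 for p, t in zip(pred, true) if p == 0 and t == 0)
            fp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 0)
            fn = sum(1 for p, t in zip(pred, true) if p == 0 and t == 1)
            return tp, tn, fp, fn

        for _ in range(100):
            n = int(rng.integers(2, 50))
            pred = rng.integers(0, 2, n)
            true = rng.integers(0, 2, n)
            if not (1 in pred and 1 in true):
                continue
            rep = evaluate(pred, true)
            tp, tn, fp, fn = brute(pred, true)
            assert (rep.tp, rep.tn, rep.fp, rep.fn) == (tp, tn, fp, fn)
            assert rep.accuracy == pytest.approx((tp + tn) / n)


class TestTanimotoKernel:
    def test_kernel_matrix_properties(self, rng):
        X = rng.integers(0, 2, size=(40, 64)).astype(float)
        from consensusvs.representations import tanimoto_matrix

        K = tanimoto_matrix(X, X)
        assert np.allclose(K, K.T)
        nonzero = X.sum(axis=1) > 0
        assert np.allclose(np.diag(K)[nonzero], 1.0)
        eigmin = np.linalg.eigvalsh(K).min()
        assert eigmin >= -1e-8

    def test_zero_vector_conventions(self):
        from consensusvs.representations import tanimoto_matrix

        X = np.array([[0, 0, 0], [1, 0, 1]], dtype=float)
        K = tanimoto_matrix(X, X)
        assert K[0, 0] == 1.0  # both empty
        assert K[0, 1] == 0.0  # one empty

    def test_rejects_non_binary(self):
        clf = TanimotoKernelSVC()
        with pytest.raises(ModelingError):
            clf.fit(np.array([[0.5, 1.0]]), np.array([1]))

    def test_tanimoto_kernel_on_descriptors_rejected(self):
        spec = ModelSpec.create("SVM", "descriptors", {"kernel": "tanimoto"})
        with pytest.raises(ModelingError):
            build_estimator(spec)


class TestTraining:
    def test_training_set_accuracy_on_separable_fixture(
        self, small_dataset, small_morgan, rf_model
    ):
        pred = rf_model.predict_labels(small_morgan)
        rep = evaluate(pred, small_dataset.labels)
        assert rep.accuracy >= 0.95

    def test_knn1_self_query_ps_is_one(self, small_dataset, small_morgan):
        spec = ModelSpec.create("KNN", "morgan", {"n_neighbors": 1}, seed=0)
        model = train(spec, small_dataset, features=small_morgan)
        active_rows = [
            i for i, lab in enumerate(small_dataset.labels) if lab == "active"
        ]
        ps = model.predict_ps(small_morgan[active_rows[:5]])
        assert np.allclose(ps, 1.0)

    @pytest.mark.parametrize(
        "algorithm,params",
        [
            ("RF", {"n_estimators": 50}),
            ("KNN", {"n_neighbors": 5}),
            ("SVM", {"kernel": "tanimoto", "C": 1.0}),
            ("MLP", {"hidden_layer_size": (20,), "solver": "lbfgs", "max_iter": 200}),
        ],
    )
    def test_ps_in_unit_interval_and_threshold_consistency(
        self, small_dataset, small_morgan, algorithm, params
    ):
        spec = ModelSpec.create(algorithm, "morgan", params, seed=3)
        model = train(spec, small_dataset, features=small_morgan)
        ps = model.predict_ps(small_morgan)
        assert np.all((ps >= 0) & (ps <= 1))
        assert np.array_equal(model.predict_labels(small_morgan), (ps >= 0.5).astype(int))

    def test_descriptor_inputs_are_scaled_in_pipeline(self, small_dataset):
        from consensusvs.modeling import features_for

        X = features_for(small_dataset, "descriptors")
        spec = ModelSpec.create("KNN", "descriptors", {"n_neighbors": 3}, seed=0)
        model = train(spec, small_dataset, features=X)
        ps = model.predict_ps(X)
        assert np.all((ps >= 0) & (ps <= 1))

    def test_single_class_dataset_rejected(self, small_dataset, small_morgan):
        actives = [c for c in small_dataset.compounds if c.label == "active"]
        ds = LabeledDataset(role="train", compounds=actives)
        spec = ModelSpec.create("RF", "morgan", {}, seed=0)
        with pytest.raises(ModelingError):
            train(spec, ds)


class TestGridSearch:
    def test_ranked_table_and_deterministic_argmax(self, small_dataset, small_morgan):
        from consensusvs.modeling import HyperparameterGrid

        grid = HyperparameterGrid("KNN", {"n_neighbors": [1, 3, 5], "weight": ["uniform"]})
        res = grid_search(
            small_dataset, "KNN", "morgan", grid=grid, seed=5, features=small_morgan
        )
        assert len(res.table) == 3
        assert res.best_params["n_neighbors"] in (1, 3, 5)
        assert res.table.iloc[0].mean_accuracy == res.table.mean_accuracy.max()

    def test_row_order_invariance(self, small_dataset, small_morgan):
        from consensusvs.modeling import HyperparameterGrid

        grid = HyperparameterGrid("KNN", {"n_neighbors": [1, 5], "weight": ["uniform"]})
        res1 = grid_search(
            small_dataset, "KNN", "morgan", grid=grid, seed=5, features=small_morgan
        )
        order = np.random.default_rng(0).permutation(len(small_dataset))
        shuffled = LabeledDataset(
            role="train",
            compounds=[small_dataset.compounds[i] for i in order],
        )
        res2 = grid_search(
            shuffled, "KNN", "morgan", grid=grid, seed=5,
            features=small_morgan[order],
        )
        assert res1.best_params == res2.best_params
        assert np.allclose(
            res1.table.mean_accuracy.values, res2.table.mean_accuracy.values
        )


class TestRepeatedSplitCV:
    def test_separable_fixture_high_accuracy(self, small_dataset, small_morgan):
        spec = ModelSpec.create("KNN", "morgan", {"n_neighbors": 5}, seed=2)
        cv = repeated_split_cv(spec, small_dataset, seed=9, features=small_morgan)
        assert len(cv.reports) == 10
        assert cv.mean_accuracy >= 0.95

    def test_fixed_seed_reproducible(self, small_dataset, small_morgan):
        spec = ModelSpec.create("RF", "morgan", {"n_estimators": 50}, seed=2)
        cv1 = repeated_split_cv(
            spec, small_dataset, n_repeats=3, seed=9, features=small_morgan
        )
        cv2 = repeated_split_cv(
            spec, small_dataset, n_repeats=3, seed=9, features=small_morgan
        )
        assert cv1.reports == cv2.reports

    def test_mean_sd_recomputable(self, small_dataset, small_morgan):
        spec = ModelSpec.create("KNN", "morgan", {"n_neighbors": 3}, seed=2)
        cv = repeated_split_cv(
            spec, small_dataset, n_repeats=4, seed=1, features=small_morgan
        )
        assert cv.mean_accuracy == pytest.approx(
            np.mean([r.accuracy for r in cv.reports])
        )

    def test_invalid_repeats(self, small_dataset, small_morgan):
        spec = ModelSpec.create("KNN", "morgan", {}, seed=0)
        with pytest.raises(ModelingError):
            repeated_split_cv(spec, small_dataset, n_repeats=0, features=small_morgan)


class TestYRandomization:
    def test_permuted_labels_collapse_to_chance(self, small_dataset, small_morgan):
        spec = ModelSpec.create(
            "RF", "morgan", {"max_features": "sqrt", "n_estimators": 100}, seed=4
        )
        accs = y_randomization(
            spec, small_dataset, n_repeats=6, seed=21, features=small_morgan
        )
        assert 0.40 <= float(np.mean(accs)) <= 0.60

    def test_unpermuted_control_stays_high(self, small_dataset, small_morgan):
        spec = ModelSpec.create(
            "RF", "morgan", {"max_features": "sqrt", "n_estimators": 100}, seed=4
        )
        cv = repeated_split_cv(
            spec, small_dataset, n_repeats=3, seed=21, features=small_morgan
        )
        assert cv.mean_accuracy >= 0.85

    def test_identical_seed_identical_list(self, small_dataset, small_morgan):
        spec = ModelSpec.create("KNN", "morgan", {"n_neighbors": 5}, seed=4)
        a1 = y_randomization(
            spec, small_dataset, n_repeats=3, seed=8, features=small_morgan
        )
        a2 = y_randomization(
            spec, small_dataset, n_repeats=3, seed=8, features=small_morgan
        )
        assert a1 == a2
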