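"""Classifier, experiment designs and prediction-table construction."""

import numpy as np
import pytest

from cogload.classify import (
    CognitiveLoadSVC,
    LabeledSet,
    baseline_comparison,
    make_design,
    order_sweep,
    run_experiment,
    train_svm,
)
from cogload.errors import InvalidTrainingError, ValidationError
from cogload.features import FeatureVector, N_FEATURES

from conftest import make_separable_dataset


class TestCognitiveLoadSVC:
    def test_separable_clusters_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (20, 2)), rng.normal(4, 0.3, (20, 2))])
        y = np.array(["class_1"] * 20 + ["class_2"] * 20)
        model = CognitiveLoadSVC().fit(X, y)
        assert (model.predict(X) == y).all()

    def test_xor_layout_with_order_4(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["class_1", "class_1", "class_2", "class_2"])
        model = CognitiveLoadSVC(order=4).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_deterministic_refit(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 5))
        y = np.where(X[:, 0] > 0, "class_2", "class_1")
        grid = rng.standard_normal((50, 5))
        p1 = CognitiveLoadSVC().fit(X, y).predict(grid)
        p2 = CognitiveLoadSVC().fit(X, y).predict(grid)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidTrainingError):
            CognitiveLoadSVC().fit(np.zeros((3, 2)) + np.arange(3)[:, None],
                                   np.array(["class_1"] * 3))

    def test_dimension_mismatch_rejected(self):
        X = np.random.default_rng(2).standard_normal((10, 4))
        y = np.array(["class_1", "class_2"] * 5)
        model = CognitiveLoadSVC().fit(X, y)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 5)))

    def test_exact_tie_predicts_rest(self):
        X = np.array([[0.0], [2.0]])
        y = np.array(["class_1", "class_2"])
        model = CognitiveLoadSVC().fit(X, y)
        model.decision_function = lambda X: np.zeros(len(np.atleast_2d(X)))
        assert list(model.predict(np.array([[1.0]]))) == ["class_1"]

    def test_zero_variance_features_ignored(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 3))
        X[:, 1] = 7.0  # constant column
        y = np.where(X[:, 0] > 0, "class_2", "class_1")
        model = CognitiveLoadSVC().fit(X, y)
        assert model.feature_mask_.tolist() == [True, False, True]
        probe = rng.standard_normal((5, 3))
        shifted = probe.copy()
        shifted[:, 1] += 100.0  # the dead feature must not influence predictions
        np.testing.assert_array_equal(model.predict(probe), model.predict(shifted))


class TestLabeledSet:
    def test_condition_label_consistency_enforced(self):
        vectors, _ = make_separable_dataset(n_subjects=2)
        with pytest.raises(ValidationError):
            LabeledSet(vectors=vectors, labels=["class_2"] + ["class_1"] * 3)

    def test_missing_condition_rejected(self):
        vectors, _ = make_separable_dataset(n_subjects=2)
        with pytest.raises(ValidationError):
            LabeledSet(vectors=vectors[:-1])

    def test_subset_preserves_pairs(self):
        vectors, _ = make_separable_dataset(n_subjects=4)
        ds = LabeledSet(vectors=vectors)
        sub = ds.subset(["S01", "S03"])
        assert sub.subject_ids == ["S01", "S03"]
        assert len(sub.vectors) == 4


class TestMakeDesign:
    def test_reference_cohort_splits(self, published_manifest):
        e1 = make_design("E1", published_manifest)
        assert len(e1.train_subject_ids) == 20 and len(e1.test_subject_ids) == 16
        assert e1.disjoint
        e2 = make_design("E2", published_manifest)
        assert len(e2.train_subject_ids) == 20 and len(e2.test_subject_ids) == 36
        assert not e2.disjoint
        e3 = make_design("E3", published_manifest)
        assert len(e3.train_subject_ids) == 10 and len(e3.test_subject_ids) == 26
        assert e3.disjoint
        e5 = make_design("E5", published_manifest)
        assert len(e5.train_subject_ids) == 18 and len(e5.test_subject_ids) == 36
        assert not e5.disjoint

    def test_average_good_split_orders_by_rate(self, published_manifest):
        e4 = make_design("E4", published_manifest)
        assert len(e4.train_subject_ids) == 10 and len(e4.test_subject_ids) == 16
        assert e4.disjoint
        by_id = {m.subject_id: m for m in published_manifest}
        train_max = max(by_id[s].X for s in e4.train_subject_ids)
        test_min = min(by_id[s].X for s in e4.test_subject_ids)
        assert train_max <= test_min
        assert all(by_id[s].group == "GOOD"
                   for s in e4.train_subject_ids + e4.test_subject_ids)

    def test_unknown_design_rejected(self, published_manifest):
        with pytest.raises(ValidationError):
            make_design("E9", published_manifest)


class TestRunExperiment:
    def test_separable_cohort_classified(self):
        vectors, metas = make_separable_dataset(n_subjects=8, gap=5.0, seed=4)
        ds = LabeledSet(vectors=vectors)
        design = make_design("E5", metas)
        table = run_experiment(design, ds, manifest=metas)
        assert set(table.columns) >= {"subject_id", "pred_rest", "pred_task", "comment"}
        assert len(table) == 8
        assert (table.comment == "correct").mean() > 0.8

    def test_empty_test_set_gives_empty_table(self):
        from cogload.classify import ExperimentDesign

        vectors, _ = make_separable_dataset(n_subjects=3, gap=5.0)
        ds = LabeledSet(vectors=vectors)
        design = ExperimentDesign("E1", ("S01", "S02", "S03"), ())
        assert run_experiment(design, ds).empty

    def test_order_sweep_contains_run_experiment(self):
        from cogload.evaluate import evaluate_prediction_table

        vectors, metas = make_separable_dataset(n_subjects=6, gap=5.0, seed=5)
        ds = LabeledSet(vectors=vectors)
        design = make_design("E1", metas)
        sweep = order_sweep(ds, design, [4], manifest=metas)
        assert len(sweep) == 1
        direct = evaluate_prediction_table(run_experiment(design, ds, manifest=metas))
        assert sweep.overall_accuracy.iloc[0] == pytest.approx(direct.overall_accuracy)

    def test_baseline_comparison_rows_and_accuracy(self):
        from cogload.features import N_FEATURES

        vectors, metas = make_separable_dataset(n_subjects=8, gap=6.0, seed=6,
                                                n_informative=N_FEATURES)
        ds = LabeledSet(vectors=vectors)
        design = make_design("E1", metas)
        table = baseline_comparison(ds, design)
        assert list(table.classifier) == ["LDA", "SVM", "kNN", "Decision tree", "Naive Bayes"]
        assert (table.overall_accuracy >= 90.0).all()
        np.testing.assert_array_equal(
            table.overall_accuracy, baseline_comparison(ds, design).overall_accuracy)

    def test_train_svm_wrapper(self):
        vectors, _ = make_separable_dataset(n_subjects=4, gap=5.0, seed=7)
        ds = LabeledSet(vectors=vectors)
        model = train_svm(ds)
        from cogload.classify import predict

        labels = predict(model, ds.vectors)
        assert set(labels) == {"class_1", "class_2"}
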