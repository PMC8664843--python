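"""Splits, metrics, CV tuning and the (M, N) filter optimizer."""

import numpy as np
import pytest

from cardiomech.core_io import FeatureMatrix
from cardiomech.model import (ASDetectionModel, FAMILIES, cross_val_f1,
                              encode_labels, evaluate, make_filter_objective,
                              optimize_filter_params, split_dataset,
                              sweep_filter_params, tune_classifier)


def separable_matrix(n_per_class=20, n_features=5, level="subject", seed=0):
    """Linearly separable two-class matrix: one prototype row per class,
    wide margin, so any split threshold inside the gap generalizes."""
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.0, 1.0, n_features)
    p1 = rng.uniform(5.0, 6.0, n_features)
    x0 = np.tile(p0, (n_per_class, 1))
    x1 = np.tile(p1, (n_per_class, 1))
    ids = [f"h{i:02d}" for i in range(n_per_class)] + \
          [f"s{i:02d}" for i in range(n_per_class)]
    labels = ["healthy"] * n_per_class + ["severe"] * n_per_class
    return FeatureMatrix(np.vstack([x0, x1]),
                         tuple(f"f{j}" for j in range(n_features)),
                         tuple(ids), tuple(labels))


class TestSplit:
    def test_45_subjects_split_36_9(self):
        rng = np.random.default_rng(0)
        labels = (["healthy"] * 13 + ["mild"] * 11 + ["moderate"] * 12
                  + ["severe"] * 9)
        ids = tuple(f"s{i:02d}" for i in range(45))
        m = FeatureMatrix(rng.standard_normal((45, 3)), ("a", "b", "c"),
                          ids, tuple(labels))
        split = split_dataset(m, "subject", 0.2, seed=1)
        assert len(split.train_ids) == 36
        assert len(split.test_ids) == 9

    def test_deterministic_under_seed(self):
        m = separable_matrix()
        a = split_dataset(m, "subject", 0.2, seed=5)
        b = split_dataset(m, "subject", 0.2, seed=5)
        assert a.test_ids == b.test_ids

    def test_chunk_level_groups_by_subject(self, e2e_matrices):
        from cardiomech.pipeline import subject_of
        m = e2e_matrices["chunk"]
        split = split_dataset(m, "chunk", 0.2, seed=0)
        train_subj = {subject_of(s) for s in split.train_ids}
        test_subj = {subject_of(s) for s in split.test_ids}
        assert not train_subj & test_subj


class TestMetrics:
    def test_closed_form_counts(self):
        y_true = [1] * 3 + [0] * 1 + [1] * 1 + [0] * 5
        y_pred = [1] * 3 + [1] * 1 + [0] * 1 + [0] * 5
        m = evaluate(y_true, y_pred, classes=(0, 1))
        assert (m.precision, m.recall, m.f1, m.accuracy) == \
            (0.75, 0.75, 0.75, 0.8)

    def test_perfect_predictions(self):
        m = evaluate([0, 1, 0, 1], [0, 1, 0, 1])
        assert m.precision == m.recall == m.accuracy == m.f1 == 1.0

    def test_constant_predictor_on_balanced_test(self):
        m = evaluate([0, 0, 1, 1], [1, 1, 1, 1])
        assert m.accuracy == 0.5 and m.recall == 1.0
        m2 = evaluate([0, 0, 1, 1], [0, 0, 0, 0])
        assert m2.accuracy == 0.5 and m2.recall == 0.0

    def test_macro_average_multiclass_vs_bruteforce(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        m = evaluate(y_true, y_pred, classes=(0, 1, 2, 3))
        f1s = []
        for k in range(4):
            tp = np.sum((y_true == k) & (y_pred == k))
            fp = np.sum((y_true != k) & (y_pred == k))
            fn = np.sum((y_true == k) & (y_pred != k))
            pr = tp / (tp + fp) if tp + fp else 0
            re = tp / (tp + fn) if tp + fn else 0
            f1s.append(2 * pr * re / (pr + re) if pr + re else 0)
        assert m.f1 == pytest.approx(np.mean(f1s))
        assert m.confusion.sum() == 200

    def test_row_normalized_confusion(self):
        m = evaluate([0, 0, 1, 1], [0, 1, 1, 1])
        rows = m.normalized_confusion().sum(axis=1)
        np.testing.assert_allclose(rows, 1.0)


class TestTuning:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_features_reach_perfect_cv_f1(self, family):
        from cardiomech.model import DEFAULT_GRIDS
        m = separable_matrix()
        small_grid = {k: v[:1] for k, v in DEFAULT_GRIDS[family].items()}
        _, _, f1 = tune_classifier(m, family, grid=small_grid, folds=5, seed=0)
        assert f1 == 1.0

    def test_shuffled_labels_score_near_chance(self):
        """Permutation null: mean CV F1 over shuffles sits at the class
        prior, far below the separable-feature score."""
        rng = np.random.default_rng(3)
        m = separable_matrix(n_per_class=30)
        scores = []
        for _ in range(6):
            shuffled = list(m.labels)
            rng.shuffle(shuffled)
            m2 = FeatureMatrix(m.values, m.feature_names, m.sample_ids,
                               tuple(shuffled))
            scores.append(cross_val_f1(m2.values, encode_labels(m2.labels),
                                       "dt", {"max_depth": 3}, folds=5, seed=0))
        assert abs(np.mean(scores) - 0.5) <= 0.15

    def test_grid_of_size_one_returns_that_config(self):
        m = separable_matrix()
        _, best, _ = tune_classifier(m, "dt", grid={"max_depth": [4]},
                                     folds=3, seed=0)
        assert best == {"max_depth": 4}

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            tune_classifier(separable_matrix(), "mlp")


class TestModelResults:
    def test_fit_returns_results_with_summary(self):
        m = separable_matrix(n_per_class=15)
        res = ASDetectionModel(m, family="dt", level="subject",
                               grid={"max_depth": [3]}, folds=3, seed=0).fit()
        assert res.metrics.f1 == 1.0
        text = res.summary()
        assert "F1" in text and "confusion" in text
        imp = res.feature_importance()
        assert set(imp) == set(m.feature_names)

    def test_from_dataframe_constructor(self):
        df = separable_matrix(n_per_class=10).to_dataframe()
        model = ASDetectionModel.from_dataframe(df, family="dt",
                                                grid={"max_depth": [2]},
                                                folds=3)
        assert model.matrix.n_samples == 20


class TestSeverityClassification:
    def test_four_class_pathway_with_overlapping_chunks(self):
        """Severity grading: 4 classes, 50%-overlap chunk augmentation,
        macro-averaged metrics and a 4x4 confusion table."""
        from cardiomech.pipeline import build_feature_matrices
        from cardiomech.synth import SynthConfig, generate_cohort
        cohort = generate_cohort(3, SynthConfig(duration=120.0), seed=5)
        recs = [r for r, _ in cohort]
        mat = build_feature_matrices(recs, M=500.0, N=10.0, overlap=0.5,
                                     levels=("chunk",))["chunk"]
        assert set(mat.labels) == {"healthy", "mild", "moderate", "severe"}
        res = ASDetectionModel(mat, family="dt", level="chunk",
                               grid={"max_depth": [5, None]},
                               folds=5, seed=0).fit()
        m = res.metrics
        assert m.confusion.shape == (4, 4)
        assert m.confusion.sum() == len(res.split.test_ids)
        np.testing.assert_allclose(m.normalized_confusion().sum(axis=1), 1.0)
        assert m.accuracy > 0.5  # far above the 4-class chance level
        for v in (m.precision, m.recall, m.f1):
            assert 0.0 <= v <= 1.0


class TestFilterOptimization:
    def test_constant_objective_returns_that_constant(self):
        res = optimize_filter_params(None, budget=12, seed=0, n_initial=8,
                                     objective=lambda M, N: 0.7)
        assert res.best_f1 == 0.7
        assert 100 <= res.M_star <= 2000 and 2 <= res.N_star <= 25

    def test_trace_deterministic_under_seed(self):
        def bumpy(M, N):
            return float(np.sin(M / 300.0) * np.cos(N / 4.0))
        a = optimize_filter_params(None, budget=15, seed=3, objective=bumpy)
        b = optimize_filter_params(None, budget=15, seed=3, objective=bumpy)
        assert a.trace == b.trace

    def test_optimizer_beats_or_matches_grid_on_analytic_surface(self):
        def surface(M, N):  # smooth unimodal, max 1.0 at (1200, 12)
            return float(np.exp(-((M - 1200) / 800) ** 2
                                - ((N - 12) / 8) ** 2))
        res = optimize_filter_params(None, budget=40, seed=2,
                                     objective=surface)
        grid = sweep_filter_params(None, M_list=np.linspace(100, 2000, 5),
                                   N_list=np.linspace(2, 25, 5),
                                   objective=surface)
        grid_best = max(t[2] for t in grid)
        assert res.best_f1 >= grid_best - 0.02

    def test_sweep_consistent_with_objective(self, bo_cohort):
        recs = [r for r, _ in bo_cohort[:2] + bo_cohort[-2:]]
        cache = {}
        obj = make_filter_objective(recs, "dt", folds=3, cache=cache)
        trace = sweep_filter_params(recs, "dt", M_list=[500], N_list=[10.0],
                                    objective=obj)
        assert trace[0][2] == obj(500, 10.0)  # memoized identity

    def test_chunk_count_nonincreasing_in_N(self, bo_cohort):
        from cardiomech.pipeline import build_feature_matrices
        recs = [r for r, _ in bo_cohort[:2]]
        n_small = build_feature_matrices(recs, M=500, N=5.0,
                                         levels=("chunk",))["chunk"].n_samples
        n_big = build_feature_matrices(recs, M=500, N=15.0,
                                       levels=("chunk",))["chunk"].n_samples
        assert n_small >= n_big

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            sweep_filter_params(None, M_list=[50], N_list=[10],
                                objective=lambda M, N: 0.0)
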