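"""ANOVA-F selection, PCA, grid-searched CV and the no-leakage guarantee."""

import json

import numpy as np
import pytest
from scipy import stats as sps

from gradiomics.errors import DataError, NotFittedError
from gradiomics.reduce_classify import (
    F_SENTINEL,
    ClassifierSpec,
    FusionPipeline,
    ReductionSpec,
    anova_f_scores,
    apply_reduction,
    fit_reduction,
    grid_search_cv,
)

FAST_FOREST = {"n_estimators": [25], "max_depth": [5]}


class TestAnovaF:
    def test_hand_computed_four_points(self):
        """{1,2} vs {3,4}: MSB = 4 (df 1), MSW = 0.5 (df 2) => F = 8."""
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        assert anova_f_scores(X, y)[0] == pytest.approx(8.0)

    def test_label_identical_feature_gets_sentinel_and_top_rank(self, rng):
        X = np.column_stack([rng.normal(size=50), np.repeat([0.0, 1.0], 25)])
        y = np.repeat([0, 1], 25)
        f = anova_f_scores(X, y)
        assert f[1] == F_SENTINEL
        assert np.argmax(f) == 1

    def test_constant_feature_zero(self, rng):
        X = np.column_stack([np.full(20, 3.3), rng.normal(size=20)])
        y = np.repeat([0, 1], 10)
        assert anova_f_scores(X, y)[0] == 0.0

    def test_independent_features_mean_near_one(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(100, 1000))
        y = np.repeat([0, 1], 50)
        mean_f = anova_f_scores(X, y).mean()
        # E[F(1, 98)] = 98/96 ~ 1.02; SE over 1000 features ~ 0.05
        assert mean_f == pytest.approx(98 / 96, abs=0.2)

    def test_equals_squared_pooled_t(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.integers(0, 2, size=40)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=40)
        f = anova_f_scores(X, y)
        t = sps.ttest_ind(X[y == 0], X[y == 1], equal_var=True).statistic
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_single_class_rejected(self, rng):
        with pytest.raises(DataError):
            anova_f_scores(rng.normal(size=(10, 2)), np.zeros(10))


class TestReduction:
    def test_pca_on_a_line_keeps_one_component(self, rng):
        t = rng.normal(size=100)
        X = np.column_stack([t, 2 * t])  # exact 1D subspace
        model = fit_reduction(X, None, ReductionSpec(kind="pca", variance=0.95))
        assert model.pca.n_components_ == 1
        assert model.pca.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_select_k_best_exact_output_width(self, rng):
        X = rng.normal(size=(60, 119))
        y = np.repeat([0, 1], 30)
        model = fit_reduction(X, y, ReductionSpec(kind="select_k_best", k=100))
        assert apply_reduction(model, X).shape == (60, 100)

    def test_k_larger_than_features_clamps_with_warning(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.repeat([0, 1], 10)
        with pytest.warns(UserWarning):
            model = fit_reduction(X, y, ReductionSpec(kind="select_k_best", k=50))
        assert apply_reduction(model, X).shape == (20, 5)

    def test_planted_feature_always_selected(self):
        rng = np.random.default_rng(41)
        y = np.repeat([0, 1], 100)
        X = rng.normal(size=(200, 51))
        X[:, 17] += 2.0 * y  # 2-SD effect
        model = fit_reduction(X, y, ReductionSpec(kind="select_k_best", k=5))
        assert 17 in model.selected_indices
        assert model.selected_indices[0] == 17  # ranked first

    def test_pca_sign_convention_largest_loading_positive(self, rng):
        X = rng.normal(size=(50, 6))
        model = fit_reduction(X, None, ReductionSpec(kind="pca", variance=0.99))
        comps = model.pca.components_ * model.signs[:, None]
        for comp in comps:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_pca_reconstruction_error_decreases(self, rng):
        X = rng.normal(size=(80, 10)) @ rng.normal(size=(10, 10))
        errors = []
        for v in (0.5, 0.8, 0.95, 0.999):
            model = fit_reduction(X, None, ReductionSpec(kind="pca", variance=v))
            Z = model.pca.transform(X)
            recon = model.pca.inverse_transform(Z)
            errors.append(float(((X - recon) ** 2).mean()))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))

    def test_selected_feature_names_propagate(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.repeat([0, 1], 15)
        names = ("a", "b", "c", "d")
        model = fit_reduction(X, y, ReductionSpec(kind="select_k_best", k=2), names)
        assert set(model.output_names) <= set(names)


class TestGridSearchCv:
    def _planted(self, seed=0, n=100, informative=2.0):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 12))
        X[:, 3] += informative * y
        return X, y

    def test_zero_effect_accuracy_near_chance(self):
        X, y = self._planted(seed=1, informative=0.0)
        cv, _ = grid_search_cv(X, y, ClassifierSpec(grid=FAST_FOREST),
                               ReductionSpec(kind="none"), folds=5, seed=1)
        assert abs(cv.mean("accuracy") - 0.5) <= 1.96 * 0.5 / np.sqrt(len(y)) + 0.05

    def test_label_leak_gives_near_perfect_accuracy(self):
        X, y = self._planted(seed=2)
        X = np.column_stack([X, y.astype(float)])  # leak
        cv, _ = grid_search_cv(X, y, ClassifierSpec(grid=FAST_FOREST),
                               ReductionSpec(kind="none"), folds=5, seed=2)
        assert cv.mean("accuracy") >= 0.95

    def test_fixed_seed_reproducible(self):
        X, y = self._planted(seed=3)
        results = []
        for _ in range(2):
            cv, _ = grid_search_cv(X, y, ClassifierSpec(grid=FAST_FOREST, seed=3),
                                   ReductionSpec(kind="select_k_best", k=5), folds=5, seed=3)
            results.append(json.dumps(cv.to_dict(), sort_keys=True))
        assert results[0] == results[1]

    def test_tie_broken_toward_simpler_model(self):
        X, y = self._planted(seed=4, informative=5.0)  # trivially separable
        spec = ClassifierSpec(grid={"n_estimators": [50, 100], "max_depth": [None, 5]})
        cv, _ = grid_search_cv(X, y, spec, ReductionSpec(kind="none"), folds=3, seed=4)
        assert cv.best_params == {"n_estimators": 50, "max_depth": 5}

    def test_too_few_samples_per_class_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        y = np.array([0, 0, 0, 0, 0, 1])
        with pytest.raises(DataError):
            grid_search_cv(X, y, ClassifierSpec(grid=FAST_FOREST), folds=5)


class TestPipelinePredictions:
    def test_probabilities_valid_and_thresholded(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.repeat([0, 1], 20)
        pipe = FusionPipeline(ReductionSpec(kind="none"),
                              ClassifierSpec(grid=FAST_FOREST)).fit(X, y)
        p = pipe.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))
        assert np.array_equal(pipe.predict(X), (p >= 0.5).astype(int))

    def test_single_tree_pure_leaves_give_binary_probabilities(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(int)
        pipe = FusionPipeline(
            ReductionSpec(kind="none"),
            ClassifierSpec(grid={"n_estimators": [1], "max_depth": [None]}),
        ).fit(X, y)
        assert set(np.round(pipe.predict_proba(X), 6)) <= {0.0, 1.0}

    def test_duplicated_test_sample_same_probability(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.repeat([0, 1], 15)
        pipe = FusionPipeline(ReductionSpec(kind="none"),
                              ClassifierSpec(grid=FAST_FOREST)).fit(X, y)
        x0 = X[:1]
        p = pipe.predict_proba(np.vstack([x0, X, x0]))
        assert p[0] == p[-1]

    def test_unfitted_pipeline_raises(self, rng):
        pipe = FusionPipeline()
        with pytest.raises(NotFittedError):
            pipe.predict_proba(rng.normal(size=(3, 4)))


class TestNoLeakage:
    def test_test_fold_labels_cannot_influence_fit(self):
        """Shuffling held-out labels leaves the fitted reduction and model
        predictions bit-identical (they see training folds only)."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 10))
        y = np.repeat([0, 1], 30)
        train_idx = np.arange(40)
        test_idx = np.arange(40, 60)

        def fit_and_probe(y_full):
            model = fit_reduction(X[train_idx], y_full[train_idx],
                                  ReductionSpec(kind="select_k_best", k=4))
            pipe = FusionPipeline(ReductionSpec(kind="select_k_best", k=4),
                                  ClassifierSpec(grid=FAST_FOREST, seed=8))
            pipe.fit(X[train_idx], y_full[train_idx])
            return model.f_scores, pipe.predict_proba(X[test_idx])

        y_shuffled = y.copy()
        y_shuffled[test_idx] = rng.permutation(y_shuffled[test_idx])
        f_a, p_a = fit_and_probe(y)
        f_b, p_b = fit_and_probe(y_shuffled)
        assert np.array_equal(f_a, f_b)
        assert np.array_equal(p_a, p_b)
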