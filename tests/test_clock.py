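import numpy as np
import pandas as pd
import pytest

from methclock.clock import (
    cv_select_lambda,
    evaluate_clock,
    kkt_max_violation,
    lambda_grid,
    lasso_coordinate_descent,
    lasso_objective,
    predict_mage,
    standardize_apply,
    standardize_fit,
    train_clock,
)
from methclock.core_io import PipelineConfig, PipelineError, SampleAnnotation
from methclock.screening import spearman_screen

from conftest import make_matrix


def frame(values, sites=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    sites = sites or [f"cg{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=sites,
                        columns=[f"S{j}" for j in range(values.shape[1])])


class TestStandardize:
    def test_hand_example(self):
        std, center, scale = standardize_fit(frame([0.2, 0.4, 0.6]))
        np.testing.assert_allclose(
            std.to_numpy()[0], [-0.70710678, 0.0, 0.70710678], atol=1e-8
        )
        assert center.iloc[0] == pytest.approx(0.4)
        assert scale.iloc[0] == pytest.approx(np.sqrt(0.08))

    def test_already_standardized_unchanged(self):
        v = np.array([-0.70710678, 0.0, 0.70710678])
        std, center, scale = standardize_fit(frame(v))
        np.testing.assert_allclose(std.to_numpy()[0], v, atol=1e-12)
        assert center.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert scale.iloc[0] == pytest.approx(1.0)

    def test_constant_feature_names_site(self):
        with pytest.raises(PipelineError, match="cg0"):
            standardize_fit(frame([0.5, 0.5, 0.5]))

    def test_apply_reproduces_fit_on_training_data(self):
        rng = np.random.default_rng(0)
        f = frame(rng.uniform(0.1, 0.9, size=(4, 6)))
        std, center, scale = standardize_fit(f)
        again = standardize_apply(f, center, scale)
        pd.testing.assert_frame_equal(std, again)

    def test_shifted_copy_moves_by_shift_over_scale(self):
        rng = np.random.default_rng(1)
        f = frame(rng.uniform(0.2, 0.6, size=(3, 5)))
        _, center, scale = standardize_fit(f)
        shifted = standardize_apply(f + 0.1, center, scale)
        base = standardize_apply(f, center, scale)
        delta = (shifted - base).to_numpy()
        expected = (0.1 / scale).to_numpy()[:, None] * np.ones((1, 5))
        np.testing.assert_allclose(delta, expected)

    def test_id_mismatch_rejected(self):
        f = frame(np.full((2, 3), 0.5) + np.arange(3) * 0.1)
        _, center, scale = standardize_fit(f)
        with pytest.raises(PipelineError, match="feature ids"):
            standardize_apply(f.iloc[::-1], center, scale)


def random_instance(n, p, seed, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / np.sqrt(((X - X.mean(0)) ** 2).sum(0))
    beta = np.zeros(p)
    beta[: max(1, p // 3)] = rng.normal(scale=5, size=max(1, p // 3))
    y = X @ beta + rng.normal(scale=noise, size=n)
    return X, y - y.mean()


class TestLassoSolver:
    def test_all_zero_at_gamma_max(self):
        X, y = random_instance(30, 8, 0)
        gmax = 2 * np.abs(X.T @ y).max()
        assert np.all(lasso_coordinate_descent(X, y, gmax * 1.0001) == 0)
        assert np.any(lasso_coordinate_descent(X, y, gmax * 0.99) != 0)

    def test_matches_ols_at_zero_penalty(self):
        X, y = random_instance(20, 5, 1)
        beta = lasso_coordinate_descent(X, y, 0.0, tol=1e-10, obj_rtol=-1.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-6)

    def test_orthonormal_design_closed_form(self):
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.normal(size=(25, 6)))
        y = rng.normal(scale=3, size=25)
        for lam in (0.5, 2.0, 8.0):
            beta = lasso_coordinate_descent(Q, y, lam, tol=1e-12, obj_rtol=-1.0)
            z = Q.T @ y
            expected = np.sign(z) * np.maximum(np.abs(z) - lam / 2, 0.0)
            np.testing.assert_allclose(beta, expected, atol=1e-10)

    def test_matches_sklearn_lasso(self):
        # independent implementation cross-check: sklearn minimizes
        # (1/2n)||y - Xb||^2 + alpha ||b||_1, i.e. gamma = 2 n alpha
        from sklearn.linear_model import Lasso

        X, y = random_instance(40, 10, 3)
        for lam in (0.2, 1.0, 4.0):
            ours = lasso_coordinate_descent(X, y, lam, tol=1e-12, obj_rtol=-1.0)
            ref = Lasso(alpha=lam / (2 * len(y)), fit_intercept=False,
                        tol=1e-12, max_iter=200_000).fit(X, y).coef_
            np.testing.assert_allclose(ours, ref, atol=1e-6)

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0])
    def test_kkt_conditions_hold(self, lam):
        X, y = random_instance(50, 12, 4)
        beta = lasso_coordinate_descent(X, y, lam, tol=1e-10, obj_rtol=-1.0)
        assert kkt_max_violation(X, y, beta, lam) <= 1e-5

    def test_objective_non_increasing_each_sweep(self):
        X, y = random_instance(30, 10, 5)
        _, history = lasso_coordinate_descent(X, y, 1.0, return_history=True)
        assert np.all(np.diff(history) <= 1e-10)

    def test_active_set_monotone_along_path_orthonormal(self):
        # on an orthonormal design the solution is coordinate-wise
        # soft-thresholding, so the active set shrinks as gamma grows
        rng = np.random.default_rng(6)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 10)))
        y = rng.normal(scale=3, size=30)
        grid = lambda_grid(Q, y, n_lambda=25)
        sizes = [
            int((lasso_coordinate_descent(Q, y, lam) != 0).sum()) for lam in grid
        ]
        assert sizes == sorted(sizes)  # grid is descending in gamma

    def test_non_finite_input_rejected(self):
        X, y = random_instance(10, 3, 7)
        X[0, 0] = np.nan
        with pytest.raises(PipelineError):
            lasso_coordinate_descent(X, y, 1.0)


class TestCrossValidation:
    def test_pure_noise_prefers_large_penalty(self):
        picks = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            X, _ = random_instance(60, 10, seed)
            y = rng.normal(size=60)
            y -= y.mean()
            lam, table = cv_select_lambda(X, y, folds=5, n_lambda=40, seed=seed)
            rank = int(np.nonzero(table["lam"].to_numpy() == lam)[0][0])
            picks.append(rank)
        # at least two of three runs pick from the sparse (top-quarter) end
        assert sorted(picks)[1] < 10

    def test_noiseless_signal_recovers_support(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 10))
        X = (X - X.mean(0)) / np.sqrt(((X - X.mean(0)) ** 2).sum(0))
        beta_true = np.array([4.0, -3.0, 2.0] + [0.0] * 7)
        y = X @ beta_true
        lam, table = cv_select_lambda(X, y, folds=5, seed=0)
        assert lam <= table["lam"].iloc[0] * 1e-2
        beta = lasso_coordinate_descent(X, y, lam)
        assert set(np.nonzero(np.abs(beta) > 0.05)[0]) >= {0, 1, 2}

    def test_same_seed_reproduces_selection(self):
        X, y = random_instance(50, 8, 9)
        a = cv_select_lambda(X, y, folds=5, seed=4)
        b = cv_select_lambda(X, y, folds=5, seed=4)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_more_folds_than_samples_rejected(self):
        X, y = random_instance(6, 3, 10)
        with pytest.raises(PipelineError, match="folds"):
            cv_select_lambda(X, y, folds=7)


class TestTrainPredict:
    def _screen(self, matrix, annotations):
        ids = [a.sample_id for a in annotations if a.condition == "normal"]
        ages = pd.Series({a.sample_id: a.age_years for a in annotations})
        return spearman_screen(matrix.restrict_samples(ids), ages[ids])

    def test_training_predictions_are_reproducible(self, small_cohort):
        matrix, annotations, _ = small_cohort
        screened = self._screen(matrix, annotations)
        cfg = PipelineConfig(seed=1)
        model, metrics = train_clock(matrix, annotations, screened, cfg)
        pred = predict_mage(model, matrix)
        ids = [a.sample_id for a in annotations if a.condition == "normal"]
        ages = np.array([a.age_years for a in annotations if a.condition == "normal"])
        again = evaluate_clock(pred[ids].to_numpy(), ages, tol=cfg.tol_years)
        assert again.pearson_r == pytest.approx(metrics.pearson_r)
        assert again.error_value == pytest.approx(metrics.error_value)

    def test_model_features_subset_of_screened(self, small_cohort):
        matrix, annotations, _ = small_cohort
        screened = self._screen(matrix, annotations)
        model, _ = train_clock(matrix, annotations, screened, PipelineConfig(seed=1))
        assert set(model.feature_ids) <= set(screened.selected_ids)
        assert len(model.feature_ids) <= model.n_train

    def test_permuted_ages_give_near_empty_model(self, small_cohort):
        matrix, annotations, _ = small_cohort
        rng = np.random.default_rng(13)
        normals = [a for a in annotations if a.condition == "normal"]
        shuffled_ages = rng.permutation([a.age_years for a in normals])
        permuted = [
            SampleAnnotation(a.sample_id, float(age), a.cohort, a.condition)
            for a, age in zip(normals, shuffled_ages)
        ]
        ids = [a.sample_id for a in permuted]
        ages = pd.Series({a.sample_id: a.age_years for a in permuted})
        screened = spearman_screen(matrix.restrict_samples(ids), ages[ids])
        if not screened.selected_ids:
            return  # nothing passes screening under the null: equally fine
        model, metrics = train_clock(matrix, permuted, screened, PipelineConfig(seed=1))
        assert len(model.feature_ids) <= 10
        assert np.isnan(metrics.pearson_r) or abs(metrics.pearson_r) < 0.6

    def test_missing_model_feature_is_error(self, small_cohort):
        matrix, annotations, _ = small_cohort
        screened = self._screen(matrix, annotations)
        model, _ = train_clock(matrix, annotations, screened, PipelineConfig(seed=1))
        reduced = matrix.values.drop(index=model.feature_ids[0])
        from methclock.core_io import BetaMatrix

        with pytest.raises(PipelineError, match=model.feature_ids[0]):
            predict_mage(model, BetaMatrix(reduced))

    def test_too_few_normals_rejected(self, small_cohort):
        matrix, annotations, _ = small_cohort
        screened = self._screen(matrix, annotations)
        few = [a for a in annotations if a.condition == "normal"][:10]
        with pytest.raises(PipelineError, match="normal"):
            train_clock(matrix, few, screened, PipelineConfig(seed=1))


class TestEvaluate:
    def test_perfect_prediction(self):
        actual = np.array([20.0, 40.0, 60.0, 80.0])
        m = evaluate_clock(actual, actual)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.error_value == 0.0
        assert m.accuracy_at_tol == 1.0
        assert m.rss == 0.0

    def test_quartile_error_uses_linear_interpolation(self):
        actual = np.zeros(4)
        predicted = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate_clock(predicted, actual)
        assert m.error_value == pytest.approx(3.25)

    def test_negated_prediction_has_r_minus_one(self):
        actual = np.array([20.0, 40.0, 60.0])
        m = evaluate_clock(-actual + 100, actual)
        assert m.pearson_r == pytest.approx(-1.0)

    def test_accuracy_counts_within_tolerance(self):
        actual = np.zeros(5)
        predicted = np.array([0.0, 2.0, 4.9, 5.0, 7.0])
        m = evaluate_clock(predicted, actual, tol=5.0)
        assert m.accuracy_at_tol == pytest.approx(0.8)

    def test_constant_prediction_reports_nan_r(self):
        m = evaluate_clock(np.full(5, 50.0), np.arange(5, dtype=float))
        assert np.isnan(m.pearson_r)
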