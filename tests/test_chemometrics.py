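"""Numerical core: scaling, OPLS, cross-validation, permutations, VIP, T²."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

import grapearoma.chemometrics as chem
from grapearoma.errors import ModelError


def _random_xy(seed, n=30, k=8):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k))
    beta = rng.normal(size=k)
    y = X @ beta + 0.3 * rng.normal(size=n)
    return X, y


class TestUvScale:
    def test_columns_become_standard(self):
        scaled, params = chem.uv_scale(np.array([[1.0], [2.0], [3.0]]), "fit")
        assert scaled.mean() == pytest.approx(0.0)
        assert scaled.std(ddof=1) == pytest.approx(1.0)

    def test_apply_reproduces_fit_on_training_data(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        scaled, params = chem.uv_scale(X, "fit")
        again, _ = chem.uv_scale(X, "apply", params)
        np.testing.assert_allclose(again, scaled, atol=1e-14)

    def test_inverse_round_trips_to_1e12(self):
        X = np.random.default_rng(1).normal(size=(10, 4)) * 5 + 3
        scaled, params = chem.uv_scale(X, "fit")
        np.testing.assert_allclose(chem.uv_unscale(scaled, params), X, atol=1e-12)

    def test_zero_variance_column_dropped_and_recorded(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [7.0, 7.0, 7.0]})
        scaled, params = chem.uv_scale(frame, "fit")
        assert params.dropped == ["b"]
        assert scaled.shape == (3, 1)

    def test_missing_column_at_apply_is_error(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 0.0, 2.0]})
        _, params = chem.uv_scale(frame, "fit")
        with pytest.raises(ModelError, match="b"):
            chem.uv_scale(frame[["a"]], "apply", params)


class TestOpls:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_no_orthogonal_components_equals_pls1(self, seed):
        """With zero orthogonal components O-PLS must reproduce one-component
        PLS1 predictions (independent implementation) to 1e-10."""
        X, y = _random_xy(seed)
        model = chem.fit_opls(X, y, n_ortho=0)
        oracle = PLSRegression(n_components=1, scale=True).fit(X, y)
        np.testing.assert_allclose(model.predict(X), oracle.predict(X).ravel(), atol=1e-10)

    @pytest.mark.parametrize("n_ortho", [1, 2, 4])
    def test_orthogonality_invariants(self, n_ortho):
        X, y = _random_xy(7)
        m = chem.fit_opls(X, y, n_ortho=n_ortho)
        assert np.linalg.norm(m.w) == pytest.approx(1.0)
        for w_o in m.w_ortho:
            assert abs(m.w @ w_o) < 1e-10
        for t_o in m.t_ortho:
            assert abs(m.t @ t_o) / (np.linalg.norm(m.t) * np.linalg.norm(t_o)) < 1e-10

    def test_exact_low_rank_data_is_fit_perfectly(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=40)
        p = rng.normal(size=6)
        X = np.outer(t, p)
        model = chem.fit_opls(X, t, n_ortho=0)
        assert model.stats["R2Y"] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(model.predict(X), t, atol=1e-8)

    def test_constant_response_rejected(self):
        X, _ = _random_xy(0)
        with pytest.raises(ModelError, match="constant"):
            chem.fit_opls(X, np.ones(X.shape[0]), n_ortho=0)

    def test_n_ortho_beyond_rank_rejected(self):
        X, y = _random_xy(0, n=30, k=4)
        with pytest.raises(ModelError, match="rank"):
            chem.fit_opls(X, y, n_ortho=4)

    def test_predicting_training_set_reproduces_fitted_values(self):
        X, y = _random_xy(5)
        m = chem.fit_opls(X, y, n_ortho=2)
        fitted = chem.uv_unscale(m.t * m.q, m.y_scaling)
        np.testing.assert_allclose(m.predict(X), fitted, atol=1e-10)

    def test_duplicated_rows_predict_identically(self):
        X, y = _random_xy(6)
        m = chem.fit_opls(X, y, n_ortho=1)
        doubled = np.vstack([X[:1], X[:1]])
        preds = m.predict(doubled)
        assert preds[0] == pytest.approx(preds[1], abs=1e-14)

    def test_predictions_invariant_to_orthogonal_subspace_perturbation(self):
        """Adding any multiple of the model's orthogonal loading direction to
        new samples must not change predictions."""
        X, y = _random_xy(8)
        m = chem.fit_opls(X, y, n_ortho=2)
        rng = np.random.default_rng(0)
        shift = np.outer(rng.normal(size=X.shape[0]), m.p_ortho[0] * m.x_scaling.std)
        np.testing.assert_allclose(m.predict(X + 5 * shift), m.predict(X), atol=1e-8)

    def test_missing_variables_listed_at_predict(self):
        frame = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 3)),
                             columns=["a", "b", "c"])
        y = frame["a"] + frame["b"]
        m = chem.fit_opls(frame, y, n_ortho=0)
        with pytest.raises(ModelError, match="c"):
            m.predict(frame[["a", "b"]])

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        frame = pd.DataFrame(np.random.default_rng(2).normal(size=(15, 4)),
                             columns=list("abcd"))
        y = frame.sum(axis=1) + 0.1 * np.random.default_rng(3).normal(size=15)
        m = chem.fit_opls(frame, y, n_ortho=1)
        m.save(tmp_path / "model.json")
        again = chem.OplsModel.load(tmp_path / "model.json")
        np.testing.assert_allclose(again.predict(frame), m.predict(frame), atol=1e-12)
        assert again.n_components_label == "1 + 1 + 0"


class TestCrossValidate:
    def test_noiseless_linear_response_is_predicted_nearly_exactly(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(35, 5))
        y = X @ rng.normal(size=5)
        cv = chem.cross_validate(X, y, folds=7, seed=0)
        assert cv.chosen_q2y >= 0.99
        # with enough components the held-out error vanishes entirely
        assert min(cv.rmsecv.values()) < 1e-6 * y.std()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_q2_never_exceeds_r2_at_same_component_count(self, seed):
        X, y = _random_xy(seed, n=25, k=10)
        for a in (0, 1, 2):
            cv = chem.cross_validate(X, y, folds=7, n_ortho_grid=[a], seed=seed)
            model = chem.fit_opls(X, y, n_ortho=a)
            assert cv.q2y[a] <= model.stats["R2Y"] + 1e-12

    def test_too_many_folds_rejected(self):
        X, y = _random_xy(0, n=5)
        with pytest.raises(ModelError, match="folds"):
            chem.cross_validate(X, y, folds=7)

    def test_fold_assignment_is_deterministic_and_balanced(self):
        y = np.random.default_rng(0).normal(size=21)
        a = chem.assign_folds(y, 7, seed=3)
        b = chem.assign_folds(y, 7, seed=3)
        np.testing.assert_array_equal(a, b)
        counts = np.bincount(a, minlength=7)
        assert counts.max() - counts.min() <= 1


class TestPermutationTest:
    def test_intercepts_match_closed_form_least_squares(self):
        X, y = _random_xy(1, n=20, k=6)
        perm = chem.permutation_test(X, y, n_ortho=1, folds=5, n_perm=30, seed=2)
        xs = np.concatenate([perm.correlations, [1.0]])
        for ys, reported in (
            (np.concatenate([perm.q2y, [perm.original_q2y]]), perm.q2_intercept),
            (np.concatenate([perm.r2y, [perm.original_r2y]]), perm.r2_intercept),
        ):
            n = xs.size
            sx, sy = xs.sum(), ys.sum()
            slope = (n * (xs * ys).sum() - sx * sy) / (n * (xs * xs).sum() - sx * sx)
            intercept = (sy - slope * sx) / n
            assert reported == pytest.approx(intercept, abs=1e-10)

    def test_requires_at_least_two_permutations(self):
        X, y = _random_xy(0)
        with pytest.raises(ModelError):
            chem.permutation_test(X, y, n_ortho=0, n_perm=1)


class TestVip:
    def test_single_variable_model_has_vip_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 1))
        y = 2 * X[:, 0] + 0.1 * rng.normal(size=20)
        scores = chem.vip(chem.fit_opls(X, y, n_ortho=0))
        assert scores.vip.iloc[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n_ortho", [0, 1, 3])
    def test_mean_squared_vip_is_one(self, n_ortho):
        X, y = _random_xy(9, n=40, k=12)
        scores = chem.vip(chem.fit_opls(X, y, n_ortho=n_ortho))
        assert (scores.vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_four_variable_model_matches_direct_formula(self):
        """Recompute VIP from the model's stored components with an
        independent direct evaluation of the defining formula."""
        X, y = _random_xy(10, n=25, k=4)
        m = chem.fit_opls(X, y, n_ortho=1)
        ys, _ = chem.uv_scale(np.asarray(y)[:, None], "fit")
        ys = ys.ravel()
        comps = [(m.w, m.t)] + list(zip(m.w_ortho, m.t_ortho))
        ssy = np.array([(t @ ys) ** 2 / (t @ t) for _, t in comps])
        k = m.w.size
        expected = np.sqrt(
            k
            * sum(s * (w / np.linalg.norm(w)) ** 2 for (w, _), s in zip(comps, ssy))
            / ssy.sum()
        )
        np.testing.assert_allclose(chem.vip(m).vip.to_numpy(), expected, atol=1e-10)

    def test_predictive_only_variant_also_normalized(self):
        X, y = _random_xy(11)
        scores = chem.vip(chem.fit_opls(X, y, n_ortho=2), kind="pred")
        assert (scores.vip**2).mean() == pytest.approx(1.0, abs=1e-8)


class TestHotelling:
    def test_clean_gaussian_flag_rate_near_one_percent(self):
        flagged = total = 0
        for seed in range(30):
            X = np.random.default_rng(100 + seed).normal(size=(200, 8))
            screen = chem.pca_hotelling_screen(X, alpha=0.01)
            flagged += int(screen.flags.sum())
            total += X.shape[0]
        assert 0.002 <= flagged / total <= 0.025

    def test_degenerate_sample_count_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 8))
        with pytest.raises(ModelError):
            chem.pca_hotelling_screen(X, n_components=3)

    def test_components_beyond_rank_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ModelError, match="rank"):
            chem.pca_hotelling_screen(X, n_components=5)

    def test_gross_outlier_flagged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6))
        X[4] *= 50
        screen = chem.pca_hotelling_screen(X)
        assert screen.flags[4]
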