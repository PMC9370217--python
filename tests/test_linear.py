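"""OLS engine, the LOO shortcut, and forward selection with the MAE_LOO gate."""

import numpy as np
import pandas as pd
import pytest

from mixqspr.errors import MissingFeatureError, SingularityError
from mixqspr.linear import (
    ForwardSelectionMLR,
    LinearModel,
    fit_ols,
    mae_loo,
    predict,
    sfs_select,
)


class TestFitOLS:
    def test_exact_linear_data(self):
        X = pd.DataFrame({"f1": [0.0, 1.0, 2.0, 3.0]})
        y = 2.0 * X["f1"] + 1.0
        model = fit_ols(X, y)
        assert model.coef[0] == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.r2 == pytest.approx(1.0)

    def test_constant_response_convention(self):
        X = pd.DataFrame({"f1": [0.0, 1.0, 2.0, 3.0]})
        model = fit_ols(X, np.full(4, 7.0))
        assert model.coef[0] == pytest.approx(0.0)
        assert model.r2 == 0.0

    def test_matches_normal_equations_oracle(self, random_regression):
        X, y = random_regression(n=20, p=3, seed=5)
        model = fit_ols(X, y)
        Xd = np.column_stack([np.ones(len(X)), X.to_numpy()])
        beta = np.linalg.inv(Xd.T @ Xd) @ Xd.T @ y
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.coef, beta[1:], atol=1e-8)

    def test_matches_statsmodels(self, random_regression):
        sm = pytest.importorskip("statsmodels.api")
        X, y = random_regression(n=40, p=4, seed=9)
        model = fit_ols(X, y)
        ref = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
        np.testing.assert_allclose(
            np.r_[model.intercept, model.coef], ref.params, atol=1e-10
        )
        np.testing.assert_allclose(
            np.r_[model.intercept_se, model.coef_se], ref.bse, atol=1e-10
        )
        assert model.r2 == pytest.approx(ref.rsquared)
        assert model.r2_adj == pytest.approx(ref.rsquared_adj)
        assert model.f_stat == pytest.approx(ref.fvalue)

    def test_singular_design_names_dependent_column(self, random_regression):
        X, y = random_regression(n=20, p=2, seed=3)
        X["dup"] = X["f1"] * 2.0
        with pytest.raises(SingularityError, match="dup"):
            fit_ols(X, y)

    def test_residuals_orthogonal_to_columns(self, random_regression):
        X, y = random_regression(n=50, p=4, seed=17)
        model = fit_ols(X, y)
        resid = y - model.predict(X)
        for col in X.columns:
            x = X[col].to_numpy()
            assert abs(x @ resid) < 1e-6 * np.linalg.norm(x) * max(np.linalg.norm(resid), 1e-12)

    def test_rho_is_points_per_variable(self, random_regression):
        X, y = random_regression(n=30, p=3, seed=2)
        assert fit_ols(X, y).rho == pytest.approx(10.0)


class TestPredict:
    def test_intercept_only_constant_vector(self):
        model = LinearModel(
            feature_names=(), coef=np.array([]), intercept=4.5,
            coef_se=np.array([]), intercept_se=0.0, r2=0, r2_adj=0,
            f_stat=0, n_train=3, rho=np.inf, residual_sd=0.0,
        )
        np.testing.assert_allclose(model.predict(pd.DataFrame(index=range(5))), 4.5)

    def test_affine_prediction(self):
        X = pd.DataFrame({"f1": [0.0, 1.0, 2.0, 3.0]})
        model = fit_ols(X, 2.0 * X["f1"] + 1.0)
        np.testing.assert_allclose(predict(model, pd.DataFrame({"f1": [0, 1, 2]})), [1, 3, 5])

    def test_missing_feature_named(self):
        X = pd.DataFrame({"f1": [0.0, 1.0, 2.0, 3.0]})
        model = fit_ols(X, 2.0 * X["f1"] + 1.0)
        with pytest.raises(MissingFeatureError, match="f1"):
            model.predict(pd.DataFrame({"other": [1.0]}))


class TestJSONRoundTrip:
    def test_serialization_preserves_prediction(self, random_regression, tmp_path):
        X, y = random_regression(n=25, p=3, seed=21)
        model = fit_ols(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = LinearModel.from_json(path)
        np.testing.assert_allclose(back.predict(X), model.predict(X), atol=1e-12)
        assert back.feature_names == model.feature_names


class TestSFS:
    def _planted(self, n=120, p_noise=10, noise=1e-6, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, 2 + p_noise)),
            columns=["f1", "f2"] + [f"n{j}" for j in range(p_noise)],
        )
        y = 3.0 * X["f1"] - 2.0 * X["f2"] + rng.normal(0, noise, n)
        return X, y

    def test_recovers_planted_signal_noise_free(self):
        X, y = self._planted()
        model = sfs_select(X, y, scoring="R2")
        assert set(model.feature_names) == {"f1", "f2"}
        named = dict(zip(model.feature_names, model.coef))
        assert named["f1"] == pytest.approx(3.0, abs=1e-3)
        assert named["f2"] == pytest.approx(-2.0, abs=1e-3)

    @pytest.mark.parametrize("scoring", ["NMAE", "NMPD", "R2_cv5", "R2_cv10"])
    def test_all_scorings_recover_planted_signal(self, scoring):
        X, y = self._planted(seed=1)
        y = y + 50.0  # NMPD needs positive responses
        model = sfs_select(X, y, scoring=scoring)
        assert set(model.feature_names) == {"f1", "f2"}

    def test_insufficient_reduction_rejected(self):
        """A candidate whose MAE_LOO cut is below the threshold stops selection."""
        rng = np.random.default_rng(4)
        n = 80
        X = pd.DataFrame({"f1": rng.normal(size=n), "weak": rng.normal(size=n)})
        # f1 dominates; 'weak' contributes far too little to cut MAE_LOO by 20%
        y = 5.0 * X["f1"] + 0.02 * X["weak"] + rng.normal(0, 1.0, n)
        model = sfs_select(X, y, scoring="R2", mae_reduction=0.20)
        assert model.feature_names == ("f1",)
        assert model.trace[-1]["accepted"] is False

    def test_no_useful_candidate_gives_intercept_only_with_warning(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame({"junk": rng.normal(size=60)})
        y = rng.normal(size=60)
        # orthogonalize y against the candidate so it cannot help, even by chance
        x = X["junk"].to_numpy()
        y = y - y.mean() - (x - x.mean()) * np.dot(y - y.mean(), x - x.mean()) / np.dot(
            x - x.mean(), x - x.mean()
        )
        model = sfs_select(X, y, scoring="R2")
        assert model.feature_names == ()
        assert model.warning is not None

    def test_single_strong_candidate(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"f1": rng.normal(size=50)})
        y = 4.0 * X["f1"] + rng.normal(0, 0.1, 50)
        model = sfs_select(X, y, scoring="R2")
        assert model.feature_names == ("f1",)

    def test_accepted_steps_each_cut_mae_loo_by_threshold(self):
        X, y = self._planted(noise=0.3, seed=6)
        model = sfs_select(X, y, scoring="R2", mae_reduction=0.05)
        for step in model.trace:
            if step["accepted"]:
                assert step["mae_loo_after"] <= 0.95 * step["mae_loo_before"] + 1e-12

    def test_path_deterministic_given_column_order(self):
        X, y = self._planted(noise=0.5, seed=7)
        a = sfs_select(X, y, scoring="R2")
        b = sfs_select(X, y, scoring="R2")
        assert a.feature_names == b.feature_names
        np.testing.assert_array_equal(a.coef, b.coef)


class TestMAELoo:
    def test_hat_identity_equals_refits(self, random_regression):
        X, y = random_regression(n=25, p=2, seed=30)
        shortcut = mae_loo(X, y)
        errors = []
        for i in range(len(X)):
            mask = np.arange(len(X)) != i
            m = fit_ols(X.iloc[mask], y[mask])
            errors.append(abs(y[i] - m.predict(X.iloc[[i]])[0]))
        assert shortcut == pytest.approx(np.mean(errors), abs=1e-10)


class TestEstimatorAPI:
    def test_sklearn_wrapper_fits_and_predicts(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        y = 2.0 * X["a"] + rng.normal(0, 0.05, 60)
        est = ForwardSelectionMLR(scoring="R2").fit(X, y)
        assert est.selected_features_ == ["a"]
        assert est.score(X, y) > 0.99  # RegressorMixin R^2

    def test_get_set_params_roundtrip(self):
        est = ForwardSelectionMLR(scoring="NMAE", mae_reduction=0.1)
        params = est.get_params()
        clone = ForwardSelectionMLR(**params)
        assert clone.get_params() == params
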