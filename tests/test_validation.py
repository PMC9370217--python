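"""LOO/LCO cross-validation, external metrics, rm2, Y-randomization, leverage AD."""

import math

import numpy as np
import pandas as pd
import pytest

from mixqspr.data import MixtureDataset
from mixqspr.linear import fit_ols
from mixqspr.validation import (
    aard,
    percent_rd,
    q2_mae_lco,
    q2_mae_loo,
    r2_pred,
    rm2_metrics,
    validate_model,
    williams,
    y_randomization,
)

from conftest import make_record


class TestQ2Loo:
    def test_exact_linear_data(self):
        X = pd.DataFrame({"f1": [0.0, 1.0, 2.0, 3.0, 4.0]})
        y = 2 * X["f1"] + 1
        q2, mae = q2_mae_loo(X, y)
        assert q2 == pytest.approx(1.0)
        assert mae == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_hand_computation(self):
        """y=[1,2,3]: deleting each point, the mean of the rest predicts it."""
        X = pd.DataFrame(index=range(3))
        q2, mae = q2_mae_loo(X, [1.0, 2.0, 3.0])
        # LOO predictions are [2.5, 2.0, 1.5]; PRESS=4.5, TSS=2
        assert q2 == pytest.approx(-1.25)
        assert mae == pytest.approx(1.0)

    def test_shortcut_equals_literal_refit_loop(self, random_regression):
        X, y = random_regression(n=30, p=2, seed=41)
        q2, mae = q2_mae_loo(X, y)
        press, abs_err = 0.0, []
        for i in range(len(X)):
            mask = np.arange(len(X)) != i
            m = fit_ols(X.iloc[mask], y[mask])
            e = y[i] - m.predict(X.iloc[[i]])[0]
            press += e * e
            abs_err.append(abs(e))
        tss = np.sum((y - y.mean()) ** 2)
        assert q2 == pytest.approx(1 - press / tss, abs=1e-10)
        assert mae == pytest.approx(np.mean(abs_err), abs=1e-10)


def _toy_mixture_data(seed=0, n_chem=3):
    """Small dataset over a few chemicals with a known linear response."""
    rng = np.random.default_rng(seed)
    hbas = [f"A{i}" for i in range(n_chem)]
    hbds = [f"B{i}" for i in range(n_chem)]
    records, rows, ys = [], [], []
    i = 0
    for a in hbas:
        for b in hbds:
            for T in (298.15, 318.15):
                i += 1
                f1 = rng.normal()
                y = 40 + 2.0 * f1 - 0.05 * T + rng.normal(0, 0.3)
                records.append(
                    make_record(
                        record_id=f"R{i:03d}", comp1=a, comp2=b, x1=0.5,
                        temperature=T, sigma=max(y, 1.0),
                    )
                )
                rows.append({"f1": f1, "temperature": T})
                ys.append(max(y, 1.0))
    ds = MixtureDataset(records=records)
    X = pd.DataFrame(rows, index=ds.record_ids)
    return ds, X, pd.Series(ys, index=ds.record_ids)


class TestQ2Lco:
    def test_pooled_predictions_match_literal_per_chemical_refits(self):
        ds, X, y = _toy_mixture_data()
        q2, mae, skipped = q2_mae_lco(ds, X, y, ["f1", "temperature"])
        assert skipped == []
        # independent literal loop
        obs, pred = [], []
        chems = sorted({r.comp1_id for r in ds} | {r.comp2_id for r in ds})
        for chem in chems:
            keep = [r.record_id for r in ds if chem not in (r.comp1_id, r.comp2_id)]
            out = [r.record_id for r in ds if chem in (r.comp1_id, r.comp2_id)]
            m = fit_ols(X.loc[keep, ["f1", "temperature"]], y.loc[keep])
            obs.extend(y.loc[out])
            pred.extend(m.predict(X.loc[out, ["f1", "temperature"]]))
        obs, pred = np.array(obs), np.array(pred)
        sse = np.sum((obs - pred) ** 2)
        sst = np.sum((obs - obs.mean()) ** 2)
        assert q2 == pytest.approx(1 - sse / sst, abs=1e-10)
        assert mae == pytest.approx(np.mean(np.abs(obs - pred)), abs=1e-10)

    def test_noise_free_linear_data_gives_q2_one(self):
        ds, X, y = _toy_mixture_data(seed=3)
        y_clean = pd.Series(
            40 + 2.0 * X["f1"] - 0.05 * X["temperature"], index=y.index
        )
        q2, mae, _ = q2_mae_lco(ds, X, y_clean, ["f1", "temperature"])
        assert q2 == pytest.approx(1.0)
        assert mae == pytest.approx(0.0, abs=1e-9)

    def test_lco_equals_loo_when_every_chemical_in_one_record(self):
        """Intercept-only model; each record's chemicals appear nowhere else."""
        records = [
            make_record(record_id=f"R{i}", comp1=f"A{i}", comp2=f"B{i}", sigma=s)
            for i, s in enumerate([30.0, 40.0, 50.0, 60.0])
        ]
        ds = MixtureDataset(records=records)
        X = pd.DataFrame(index=ds.record_ids)
        y = ds.sigma()
        q2_lco, mae_lco, _ = q2_mae_lco(ds, X, y, [])
        q2_loo, mae_loo_v = q2_mae_loo(X, y)
        # pooled vector duplicates each record (held out once per chemical)
        assert q2_lco == pytest.approx(q2_loo)
        assert mae_lco == pytest.approx(mae_loo_v)


class TestExternalMetrics:
    def test_r2_pred_cases(self):
        assert r2_pred([50, 60], [50, 60], 54.0) == pytest.approx(1.0)
        assert r2_pred([50, 60], [54, 54], 54.0) == pytest.approx(0.0)
        assert r2_pred([50, 60], [52, 57], 54.0) == pytest.approx(0.75)

    def test_r2_pred_zero_denominator(self):
        with pytest.raises(ValueError):
            r2_pred([54.0, 54.0], [50.0, 51.0], 54.0)

    def test_aard_cases(self):
        assert aard([50.0], [50.0]) == 0.0
        assert aard([50.0], [55.0]) == pytest.approx(10.0)
        assert aard([40.0, 50.0], [44.0, 45.0]) == pytest.approx(10.0)

    def test_percent_rd_signed(self):
        np.testing.assert_allclose(percent_rd([50, 50], [55, 45]), [10.0, -10.0])

    def test_order_invariance(self, rng):
        obs = rng.uniform(30, 70, 20)
        pred = obs + rng.normal(0, 2, 20)
        perm = rng.permutation(20)
        assert aard(obs, pred) == pytest.approx(aard(obs[perm], pred[perm]))
        assert r2_pred(obs, pred, 50.0) == pytest.approx(r2_pred(obs[perm], pred[perm], 50.0))


def _rm2_oracle(y_obs, y_pred):
    """Independent re-implementation of the scaled rm2 formulas."""
    def scale(v):
        v = np.asarray(v, float)
        return (v - v.min()) / (v.max() - v.min())

    def r0sq(y, x):
        k = np.sum(x * y) / np.sum(x * x)
        return 1 - np.sum((y - k * x) ** 2) / np.sum((y - np.mean(y)) ** 2)

    yo, yp = scale(y_obs), scale(y_pred)
    r2 = np.corrcoef(yo, yp)[0, 1] ** 2
    rm2 = r2 * (1 - np.sqrt(max(r2 - r0sq(yo, yp), 0)))
    rm2p = r2 * (1 - np.sqrt(max(r2 - r0sq(yp, yo), 0)))
    return rm2, rm2p, abs(rm2 - rm2p)


class TestRm2:
    def test_perfect_predictions(self):
        y = [30.0, 40.0, 50.0, 60.0]
        out = rm2_metrics(y, y)
        assert out["rm2"] == pytest.approx(1.0)
        assert out["delta_rm2"] == pytest.approx(0.0)

    def test_offset_removed_by_scaling(self):
        y = np.array([30.0, 42.0, 55.0, 61.0])
        out = rm2_metrics(y, 1.7 * y + 12.0)
        assert out["rm2"] == pytest.approx(1.0)

    def test_matches_independent_oracle(self, rng):
        obs = rng.uniform(30, 70, 10)
        pred = obs + rng.normal(0, 4, 10)
        out = rm2_metrics(obs, pred)
        rm2, rm2p, delta = _rm2_oracle(obs, pred)
        assert out["rm2"] == pytest.approx(rm2, abs=1e-10)
        assert out["rm2_prime"] == pytest.approx(rm2p, abs=1e-10)
        assert out["delta_rm2"] == pytest.approx(delta, abs=1e-10)


class TestYRandomization:
    def test_strong_signal_gives_high_crp2(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = 40 + X @ np.array([5.0, -4.0, 3.0]) + rng.normal(0, 0.5, 200)
        report = y_randomization(X, y, n_runs=200, rng_seed=1)
        assert report.crp2 > 0.8

    def test_pure_noise_gives_low_crp2(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = rng.normal(size=100)
        report = y_randomization(X, y, n_runs=200, rng_seed=3)
        assert report.crp2 < 0.3

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=list("ab"))
        y = X["a"] * 2 + rng.normal(0, 1, 50)
        a = y_randomization(X, y, n_runs=50, rng_seed=7)
        b = y_randomization(X, y, n_runs=50, rng_seed=7)
        assert a.crp2 == b.crp2 and a.mean_randomized_r2 == b.mean_randomized_r2

    def test_zero_runs_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            y_randomization(X, [1, 2, 3, 4], n_runs=0)

    def test_crp2_bounded_by_model_r(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(80, 2)), columns=list("ab"))
        y = X["a"] - X["b"] + rng.normal(0, 1, 80)
        report = y_randomization(X, y, n_runs=100, rng_seed=11)
        assert report.crp2 <= report.model_r + 1e-12


class TestWilliams:
    def test_single_centered_predictor_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        x = x - x.mean()
        X = pd.DataFrame({"f1": x})
        y = 3 * x + rng.normal(0, 0.5, 25)
        model = fit_ols(X, y)
        report = williams(model, X, y)
        h = report.table.loc[report.table["set"] == "train", "leverage"].to_numpy()
        expected = 1 / 25 + x**2 / np.sum(x**2)
        np.testing.assert_allclose(h, expected, atol=1e-12)

    def test_leverages_sum_to_parameter_count(self, random_regression):
        X, y = random_regression(n=40, p=3, seed=51)
        model = fit_ols(X, y)
        report = williams(model, X, y)
        train_h = report.table.loc[report.table["set"] == "train", "leverage"]
        assert train_h.sum() == pytest.approx(model.n_features + 1)
        assert ((train_h >= 0) & (train_h <= 1)).all()

    def test_record_at_centroid_has_minimal_leverage(self, random_regression):
        X, y = random_regression(n=30, p=2, seed=52)
        model = fit_ols(X, y)
        centroid = X.mean().to_frame().T
        report = williams(model, X, y, probe=(centroid, [float(np.mean(y))]))
        h = report.table.loc[report.table["set"] == "probe", "leverage"].iloc[0]
        assert h == pytest.approx(1 / len(X))

    def test_h_star_and_flags(self, random_regression):
        X, y = random_regression(n=40, p=3, seed=53)
        model = fit_ols(X, y)
        report = williams(model, X, y)
        assert report.h_star == pytest.approx(3 * (3 + 1) / 40)
        t = report.table
        assert (t["structural_outlier"] == (t["leverage"] > report.h_star)).all()


class TestValidateModel:
    def test_full_battery_on_synthetic_data(self):
        ds, X, y = _toy_mixture_data(seed=8)
        model = fit_ols(X[["f1", "temperature"]], y)
        half = len(ds) // 2
        train_ids = ds.record_ids[:half]
        test_ids = ds.record_ids[half:]
        report = validate_model(
            model,
            ds.subset(train_ids),
            X.loc[train_ids],
            y.loc[train_ids],
            {"test": (X.loc[test_ids], y.loc[test_ids])},
        )
        d = report.to_dict()
        assert d["q2_loo"] <= 1 and d["q2_lco"] <= 1
        assert d["r2_pred_test"] <= 1
        assert d["aard_train"] >= 0 and d["aard_test"] >= 0
        assert not math.isnan(d["rm2_test"])
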