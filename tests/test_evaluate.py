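"""Fit statistics, correlation tables, validation reporting."""

import numpy as np
import pandas as pd
import pytest

from ampmyield import (correlation_stats, correlation_table, fit, fit_stats,
                       predict_daily, preset_model, rmse, sigma_check,
                       validation_report)
from ampmyield.evaluate import render_report
from ampmyield.io import load_model, save_model


class TestRmse:
    def test_perfect_predictions(self):
        assert rmse([1, 2, 3], [1, 2, 3], p=1) == 0.0

    def test_direct_evaluation(self):
        # SSE = 1, n - p = 2 -> sqrt(1/2)
        assert rmse([1, 2, 3], [1, 2, 4], p=1) == pytest.approx(np.sqrt(0.5))

    def test_homogeneity_in_residuals(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = obs + np.array([0.1, -0.2, 0.3, -0.1])
        pred2 = obs + 2 * (pred - obs)
        assert rmse(obs, pred2, 1) == pytest.approx(2 * rmse(obs, pred, 1))

    def test_n_not_greater_than_p_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2], p=2)

    def test_eq4_identity(self):
        rng = np.random.default_rng(21)
        obs, pred = rng.normal(size=50), rng.normal(size=50)
        p = 3
        sse = float(np.sum((obs - pred) ** 2))
        assert rmse(obs, pred, p) ** 2 * (50 - p) == pytest.approx(sse, rel=1e-9)


class TestCorrelationStats:
    def test_perfect_agreement(self):
        r2, r_pct, _ = correlation_stats([1, 2, 3, 4], [1, 2, 3, 4])
        assert r_pct == pytest.approx(100.0)
        assert r2 == pytest.approx(1.0)

    def test_sign_flip_reported_via_flag(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        st = fit_stats(obs, -obs, p=1)
        assert st.r_y_yhat == pytest.approx(100.0)
        assert st.sign == -1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(22)
        obs = rng.normal(size=10)
        pred = 0.5 * obs + rng.normal(size=10)
        r2, r_pct, sigma = correlation_stats(obs, pred)
        # independent computation from raw sums
        n = 10
        sxy = np.sum(obs * pred) - np.sum(obs) * np.sum(pred) / n
        sxx = np.sum(obs**2) - np.sum(obs) ** 2 / n
        syy = np.sum(pred**2) - np.sum(pred) ** 2 / n
        r_ref = sxy / np.sqrt(sxx * syy)
        assert r_pct == pytest.approx(100 * abs(r_ref), abs=1e-10)
        assert sigma == pytest.approx(np.sqrt(syy / (n - 1)), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_stats([1, 1, 1], [1, 2, 3])


class TestSigmaCheck:
    def test_boundary_passes(self):
        st = fit_stats([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], p=1)
        assert st.sigma_yhat == pytest.approx(st.sd_observed)
        assert sigma_check(st)

    def test_training_least_squares_always_passes(self, calib):
        # var(fitted) <= var(observed) is a consequence of the
        # orthogonality of least-squares residuals to the fitted values
        for trait, session in (("fat", "am"), ("mufa", "pm"), ("milk", "am")):
            fm = fit(calib, preset_model(trait, session))
            obs = calib["milk_daily" if trait == "milk"
                        else f"yield_daily_{trait}"]
            st = fit_stats(obs, predict_daily(fm, calib), fm.p)
            assert sigma_check(st)

    def test_inflated_predictions_fail(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        st = fit_stats(obs, 3.0 * obs, p=1)
        assert not sigma_check(st)


class TestCorrelationTable:
    def test_identical_sessions_give_100(self, validation):
        v = validation.copy()
        for col in v.columns:
            if col.startswith("content_pm") or col.startswith("yield_pm"):
                v[col] = v[col.replace("_pm_", "_am_")]
        v["milk_pm"] = v["milk_am"]
        v["milk_daily"] = 2 * v["milk_am"]
        for t in ("fat", "sfa"):
            v[f"yield_daily_{t}"] = 2 * v[f"yield_am_{t}"]
        tab = correlation_table(v)
        milk = tab[(tab.trait == "milk")].iloc[0]
        assert milk["am_pm"] == pytest.approx(100.0)
        assert milk["am_daily"] == pytest.approx(100.0)

    def test_independent_equal_variance_components(self):
        # daily = AM + PM with independent equal-variance parts:
        # corr(AM, daily) -> 1/sqrt(2)
        rng = np.random.default_rng(23)
        n = 40_000
        am, pm = rng.normal(10, 2, n), rng.normal(10, 2, n)
        v = pd.DataFrame({
            "milk_am": am, "milk_pm": pm, "milk_daily": am + pm,
        })
        for t in ("fat", "sfa", "mufa", "ufa", "scfa", "mcfa", "lcfa",
                  "c18_1_cis9"):
            ya, yp = rng.normal(300, 40, n), rng.normal(300, 40, n)
            v[f"content_am_{t}"] = rng.normal(4, 0.5, n)
            v[f"content_pm_{t}"] = rng.normal(4, 0.5, n)
            v[f"yield_am_{t}"] = ya
            v[f"yield_pm_{t}"] = yp
            v[f"yield_daily_{t}"] = ya + yp
        tab = correlation_table(v)
        milk = tab[tab.trait == "milk"].iloc[0]
        assert milk["am_daily"] == pytest.approx(100 / np.sqrt(2), abs=1.0)
        assert abs(milk["am_pm"]) < 2.0

    def test_yield_correlations_exceed_content_correlations(self, validation):
        # both milkings share the cow's milk volume, so yields co-vary
        # more strongly than contents
        tab = correlation_table(validation)
        y = tab[(tab.kind == "yield") & (tab.trait != "milk")]
        c = tab[tab.kind == "content"]
        assert y["am_daily"].mean() > c["am_daily"].mean()

    def test_too_few_records_rejected(self, validation):
        with pytest.raises(ValueError):
            correlation_table(validation.head(2))


@pytest.fixture(scope="module")
def fitted(calib):
    return {
        ("fat", "am"): fit(calib, preset_model("fat", "am")),
        ("fat", "pm"): fit(calib, preset_model("fat", "pm")),
    }


class TestValidationReport:

    def test_calibration_rows_reuse_fit_statistics(self, fitted, calib):
        rep = validation_report(fitted, {"calib": calib})
        row = rep[(rep.trait == "fat") & (rep.session == "am")
                  & (rep.dataset == "calib")].iloc[0]
        fm = fitted[("fat", "am")]
        assert row["rmse"] == pytest.approx(
            np.sqrt(fm.sse / (fm.n - fm.p)), rel=1e-9
        )

    def test_row_permutation_invariance(self, fitted, calib, validation):
        rng = np.random.default_rng(24)
        perm = validation.iloc[rng.permutation(len(validation))]
        a = validation_report(fitted, {"val": validation})
        b = validation_report(fitted, {"val": perm})
        pd.testing.assert_frame_equal(a, b)

    def test_missing_models_reported_not_raised(self, fitted, calib):
        rep = validation_report(fitted, {"calib": calib})
        absent = rep[(rep.trait == "milk")]
        assert absent["rmse"].isna().all()

    def test_report_from_saved_models_matches(self, fitted, calib, tmp_path):
        reloaded = {}
        for key, fm in fitted.items():
            path = tmp_path / f"{key[0]}_{key[1]}.csv"
            save_model(fm, path)
            reloaded[key] = load_model(path)
        a = validation_report(fitted, {"calib": calib})
        b = validation_report(reloaded, {"calib": calib})
        pd.testing.assert_frame_equal(a, b)

    def test_render_is_two_decimal_text(self, fitted, calib):
        text = render_report(validation_report(fitted, {"calib": calib}))
        assert "rmse" in text and "r_y_yhat" in text


def test_validation_r_not_above_calibration_on_average():
    """Fitting and scoring in-sample is optimistic: across replicate
    populations of identical structure, out-of-sample R_y,yhat does not
    exceed in-sample R_y,yhat on average."""
    from ampmyield import (SimulationConfig, estimate_b_all, expected_split,
                           make_s_dataset, make_t_dataset, simulate_herds)
    diffs = []
    for seed in range(6):
        base = dict(n_herds=4, cows_per_herd=12, test_days_per_cow=4)
        tr_a = simulate_herds(SimulationConfig(**base, seed=3000 + seed))
        tr_b = simulate_herds(SimulationConfig(**base, seed=4000 + seed))
        b = estimate_b_all(make_t_dataset(tr_a))
        cal = expected_split(make_s_dataset(tr_a), b)
        val = expected_split(make_s_dataset(tr_b), b)
        for trait, session in (("fat", "am"), ("ufa", "pm")):
            fm = fit(cal, preset_model(trait, session))
            resp = f"yield_daily_{trait}"
            r_cal = fit_stats(cal[resp], predict_daily(fm, cal), fm.p).r_y_yhat
            r_val = fit_stats(val[resp], predict_daily(fm, val), fm.p).r_y_yhat
            diffs.append(r_cal - r_val)
    assert np.mean(diffs) >= 0.0
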