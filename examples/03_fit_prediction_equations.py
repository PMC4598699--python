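"""Fit the shipped single-milking prediction equations and validate them.

Fits the preset best-fit model forms for daily fat yield (one per
milking session) on decomposed calibration data, then scores them on an
independent, fully observed population.
"""

from ampmyield import (SimulationConfig, estimate_b_all, expected_split,
                       fit, fit_stats, format_model, make_s_dataset,
                       make_t_dataset, make_validation_dataset, predict_daily,
                       preset_model, sigma_check, simulate_herds)

train_truth = simulate_herds(SimulationConfig(n_herds=20, cows_per_herd=25,
                                              test_days_per_cow=8, seed=21))
b = estimate_b_all(make_t_dataset(train_truth))
calib = expected_split(make_s_dataset(train_truth), b)

campaign = make_validation_dataset(
    simulate_herds(SimulationConfig(n_herds=15, cows_per_herd=23,
                                    test_days_per_cow=2, seed=22))
)

for session in ("am", "pm"):
    spec = preset_model("fat", session)
    print(f"fat / {session.upper()} model: {format_model(spec)}")
    fm = fit(calib, spec)
    st_cal = fit_stats(calib["yield_daily_fat"],
                       predict_daily(fm, calib), fm.p)
    st_val = fit_stats(campaign["yield_daily_fat"],
                       predict_daily(fm, campaign), fm.p)
    print(f"  calibration (n={st_cal.n}, p={st_cal.p}): "
          f"R_y,yhat {st_cal.r_y_yhat:.1f}%, RMSE {st_cal.rmse:.0f} g/day, "
          f"sigma_yhat {st_cal.sigma_yhat:.0f} <= SD {st_cal.sd_observed:.0f}"
          f" -> {'ok' if sigma_check(st_cal) else 'INFLATED'}")
    print(f"  validation  (n={st_val.n}):        "
          f"R_y,yhat {st_val.r_y_yhat:.1f}%, RMSE {st_val.rmse:.0f} g/day")

print("\nR_y,yhat is the observed-predicted correlation in percent; the")
print("prediction SD must not exceed the observed SD, otherwise the model")
print("manufactures variance the cows do not have.")
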