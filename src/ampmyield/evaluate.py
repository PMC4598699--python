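"""Goodness-of-fit and validation statistics for daily-yield models.

Conventions follow standard milk-recording practice:

* RMSE uses the model degrees of freedom, ``sqrt(SSE / (n - p))`` with
  ``p`` the number of estimated parameters including the intercept;
* the headline accuracy figure is the observed-predicted correlation
  ``R_y,yhat`` in percent (the square root of the coefficient of
  determination when that is defined as a squared Pearson correlation);
* a well-behaved model's prediction SD ``sigma_yhat`` should approach,
  but never exceed, the SD of the observed daily yields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .modelfit import FittedModel, predict_daily, response_column
from .traits import ALL_TRAITS, CONTENT_TRAITS

__all__ = [
    "FitStats", "rmse", "correlation_stats", "sigma_check",
    "fit_stats", "correlation_table", "validation_report",
]


@dataclass(frozen=True)
class FitStats:
    """Summary of one model on one dataset."""

    n: int
    p: int
    sse: float
    rmse: float
    r2: float
    r_y_yhat: float  # percent, absolute value of the Pearson correlation
    sign: int  # sign of the underlying correlation
    sigma_yhat: float
    sd_observed: float


def rmse(observed, predicted, p: int) -> float:
    """Root-mean-square error with ``n - p`` in the denominator."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = len(obs)
    if n != len(pred):
        raise ValueError("observed and predicted lengths differ")
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    sse = float(np.sum((obs - pred) ** 2))
    return float(np.sqrt(sse / (n - p)))


def correlation_stats(observed, predicted) -> tuple[float, float, float]:
    """``(r2, r_y_yhat_percent, sigma_yhat)`` for an observed/predicted pair.

    ``r2`` is the squared Pearson correlation; ``r_y_yhat`` its square
    root in percent (sign dropped — callers needing the sign take it from
    :func:`fit_stats`).  ``sigma_yhat`` is the SD of the predictions
    (``ddof=1``).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("zero variance in observed or predicted values")
    r = float(sps.pearsonr(obs, pred).statistic)
    return r * r, 100.0 * abs(r), float(np.std(pred, ddof=1))


def sigma_check(stats: FitStats) -> bool:
    """Prediction-SD criterion: pass iff ``sigma_yhat <= sd_observed``."""
    return stats.sigma_yhat <= stats.sd_observed


def fit_stats(observed, predicted, p: int) -> FitStats:
    """All statistics for one model evaluated on one dataset."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    r2, r_pct, sigma = correlation_stats(obs, pred)
    sign = 1 if sps.pearsonr(obs, pred).statistic >= 0 else -1
    sse = float(np.sum((obs - pred) ** 2))
    return FitStats(
        n=len(obs), p=p, sse=sse, rmse=rmse(obs, pred, p),
        r2=r2, r_y_yhat=r_pct, sign=sign,
        sigma_yhat=sigma, sd_observed=float(np.std(obs, ddof=1)),
    )


def correlation_table(validation: pd.DataFrame) -> pd.DataFrame:
    """AM-PM, AM-daily and PM-daily Pearson correlations (%), per trait.

    Computed on fully observed validation records, separately for contents
    (g/dL) and yields (g/day; kg/day for milk, which has no content rows).
    """
    if len(validation) < 3:
        raise ValueError("need at least 3 validation records")
    rows = []

    def r_pct(a, b) -> float:
        return 100.0 * float(sps.pearsonr(a, b).statistic)

    milk_am = validation["milk_am"]
    milk_pm = validation["milk_pm"]
    milk_d = validation["milk_daily"]
    rows.append({
        "trait": "milk", "kind": "yield",
        "am_pm": r_pct(milk_am, milk_pm),
        "am_daily": r_pct(milk_am, milk_d),
        "pm_daily": r_pct(milk_pm, milk_d),
    })
    for t in CONTENT_TRAITS:
        for kind, prefix in (("content", "content"), ("yield", "yield")):
            am = validation[f"{prefix}_am_{t}"]
            pm = validation[f"{prefix}_pm_{t}"]
            if kind == "content":
                daily = 0.5 * am + 0.5 * pm
            else:
                daily = validation[f"yield_daily_{t}"]
            rows.append({
                "trait": t, "kind": kind,
                "am_pm": r_pct(am, pm),
                "am_daily": r_pct(am, daily),
                "pm_daily": r_pct(pm, daily),
            })
    out = pd.DataFrame(rows)
    bad = out[["am_pm", "am_daily", "pm_daily"]].abs().gt(100 + 1e-9)
    assert not bad.any().any()
    return out


def validation_report(
    fitted: dict[tuple[str, str], FittedModel],
    datasets: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Calibration/validation statistics per trait x session x dataset.

    ``fitted`` maps ``(trait, session)`` to a fitted model; ``datasets``
    maps a dataset label (e.g. ``calib``, ``test``, ``val``) to records
    carrying the needed fields.  Traits with no fitted model are reported
    with NaN statistics rather than raising.  Columns: sigma_yhat, rmse,
    r_y_yhat (%), n, p.
    """
    rows = []
    for trait in ALL_TRAITS:
        for session in ("am", "pm"):
            fm = fitted.get((trait, session))
            for name, data in datasets.items():
                row = {"trait": trait, "session": session, "dataset": name}
                if fm is None:
                    row.update({"sigma_yhat": np.nan, "rmse": np.nan,
                                "r_y_yhat": np.nan, "n": len(data), "p": np.nan})
                else:
                    obs = data[response_column(trait)].to_numpy(dtype=float)
                    pred = predict_daily(fm, data)
                    st = fit_stats(obs, pred, fm.p)
                    row.update({"sigma_yhat": st.sigma_yhat, "rmse": st.rmse,
                                "r_y_yhat": st.r_y_yhat, "n": st.n, "p": st.p})
                rows.append(row)
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame) -> str:
    """Aligned text rendering of a validation report, 2-decimal numbers."""
    df = report.copy()
    for c in ("sigma_yhat", "rmse", "r_y_yhat"):
        df[c] = df[c].map(lambda v: f"{v:.2f}" if np.isfinite(v) else "-")
    return df.to_string(index=False)
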