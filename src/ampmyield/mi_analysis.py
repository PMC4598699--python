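"""How much milking-interval variation do production traits explain?

Prediction equations that omit the milking interval (MI) rest on the
claim that its information content is largely recoverable from traits
recorded anyway: the bigger the share of the 24 h day preceding a
milking, the more milk that milking carries, and — through dilution — the
lower its fat content.  This module quantifies that claim by regressing
the MI (hours preceding the chosen session's milking) on five nested
covariate sets:

1. daily milk yield;
2. + the session's milk yield;
3. + the session's fat content (g/dL);
4. + days-in-milk classes;
5. + parity classes.

Because the models are nested least squares, R-squared is non-decreasing
along the sequence; the interesting quantity is where it jumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .modelfit import _independent_columns, dim_class

__all__ = ["MIRegressionReport", "mi_nested_regressions"]

MODEL_LABELS = (
    "Milk daily yield",
    "+ Milk (AM or PM) yield",
    "+ FAT (AM or PM) (g/dL of milk)",
    "+ DIM",
    "+ parity",
)


@dataclass(frozen=True)
class MIRegressionReport:
    """R-squared (in %) of the five nested MI regressions."""

    labels: tuple[str, ...]
    r2_percent: tuple[float, ...]
    #: partial-F p-value of each added block (first entry vs intercept-only)
    block_p_values: tuple[float, ...]
    #: True where the added block is significant at 0.05
    significant: tuple[bool, ...]
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.labels,
            "r2_percent": self.r2_percent,
            "block_p_value": self.block_p_values,
            "significant_05": self.significant,
        })


def _indicators(values: np.ndarray) -> list[np.ndarray]:
    return [(values == lv).astype(float) for lv in np.unique(values)]


def _ols_sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    keep = _independent_columns(X)
    Xk = X[:, keep]
    coef, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ coef
    return float(resid @ resid), len(keep)


def mi_nested_regressions(
    records: pd.DataFrame, session: str = "am"
) -> MIRegressionReport:
    """Fit the five nested MI regressions and report R-squared in %.

    ``records`` must carry ``mi_<session>`` (hours), ``milk_am``/``milk_pm``,
    the session fat content ``content_<session>_fat``, ``dim`` and
    ``parity``.  DIM and parity enter as class effects.
    """
    if session not in ("am", "pm"):
        raise ValueError(f"session must be 'am' or 'pm', got {session!r}")
    y = records[f"mi_{session}"].to_numpy(dtype=float)
    n = len(y)
    if np.unique(y).size < 2:
        raise ValueError("milking interval has no variance to explain")

    daily = (records["milk_am"] + records["milk_pm"]).to_numpy(dtype=float)
    milk_s = records[f"milk_{session}"].to_numpy(dtype=float)
    fat_s = records[f"content_{session}_fat"].to_numpy(dtype=float)
    dimc = dim_class(records["dim"])
    par = np.minimum(records["parity"].to_numpy(dtype=int), 3)

    blocks = [
        [daily],
        [milk_s],
        [fat_s],
        _indicators(dimc),
        _indicators(par),
    ]

    sst = float(np.sum((y - y.mean()) ** 2))
    cols: list[np.ndarray] = [np.ones(n)]
    sse_prev, p_prev = _ols_sse(np.column_stack(cols), y)
    r2s, pvals, sig = [], [], []
    for block in blocks:
        cols.extend(block)
        sse, p = _ols_sse(np.column_stack(cols), y)
        r2s.append(100.0 * (1.0 - sse / sst))
        df_num = p - p_prev
        df_den = n - p
        if df_num <= 0 or df_den <= 0 or sse <= 0:
            pval = np.nan
        else:
            f = ((sse_prev - sse) / df_num) / (sse / df_den)
            pval = float(sps.f.sf(f, df_num, df_den))
        pvals.append(pval)
        sig.append(bool(np.isfinite(pval) and pval < 0.05))
        sse_prev, p_prev = sse, p

    r2s = np.maximum.accumulate(np.asarray(r2s))  # guard rounding jitter only
    return MIRegressionReport(
        labels=MODEL_LABELS,
        r2_percent=tuple(float(v) for v in r2s),
        block_p_values=tuple(pvals),
        significant=tuple(sig),
        n=n,
    )
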