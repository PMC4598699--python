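"""Published descriptive statistics of the three study populations.

These tables reproduce the printed per-trait means and SDs of the
Luxembourg calibration population (79,971 mixed-scheme test-day records),
the Luxembourg validation campaign (687 cow days with both milkings
observed) and the Walloon validation population (1,079,318 records).
They serve two purposes: they document the magnitudes the synthetic
generator aims for, and they support arithmetic consistency checks —
within each population the printed daily yield must equal the sum of the
printed AM and PM yields (up to print-precision rounding), and the
saturated share of fat follows from the printed SFA and fat contents.

Contents are g/dL of milk, yields g/day; milk rows carry kg/day in the
yield columns and no content.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

__all__ = ["reference_stats", "fixture_checks", "DATASETS"]

DATASETS = ("calibration", "lux", "wal")

# dataset, trait, session, content_mean, content_sd, yield_mean, yield_sd
_REFERENCE_CSV = """\
dataset,trait,session,content_mean,content_sd,yield_mean,yield_sd
calibration,milk,am,,,12.79,4.27
calibration,milk,pm,,,13.57,4.41
calibration,milk,daily,,,26.36,8.33
calibration,fat,am,4.11,0.71,515.31,164.29
calibration,fat,pm,4.55,0.78,605.64,191.21
calibration,fat,daily,4.34,0.75,1120.94,340.33
calibration,sfa,am,2.76,0.56,344.33,111.28
calibration,sfa,pm,2.95,0.60,392.11,127.91
calibration,sfa,daily,2.86,0.58,736.41,229.39
calibration,mufa,am,1.15,0.24,144.14,53.26
calibration,mufa,pm,1.36,0.29,181.38,64.96
calibration,mufa,daily,1.26,0.27,325.55,114.28
calibration,ufa,am,1.34,0.27,168.57,61.34
calibration,ufa,pm,1.59,0.32,210.87,73.76
calibration,ufa,daily,1.47,0.29,379.44,130.42
calibration,scfa,am,0.38,0.08,47.77,16.50
calibration,scfa,pm,0.40,0.08,53.83,18.69
calibration,scfa,daily,0.39,0.08,101.57,33.93
calibration,mcfa,am,2.16,0.47,268.89,87.51
calibration,mcfa,pm,2.29,0.50,302.83,99.40
calibration,mcfa,daily,2.22,0.49,571.72,179.28
calibration,lcfa,am,1.58,0.35,198.89,75.77
calibration,lcfa,pm,1.87,0.42,249.47,92.22
calibration,lcfa,daily,1.73,0.39,448.39,162.72
calibration,c18_1_cis9,am,0.75,0.19,94.13,38.48
calibration,c18_1_cis9,pm,0.91,0.23,120.85,48.53
calibration,c18_1_cis9,daily,0.83,0.21,214.98,84.65
lux,milk,am,,,12.83,4.46
lux,milk,pm,,,15.13,5.18
lux,milk,daily,,,27.96,9.41
lux,fat,am,4.27,0.80,537.47,187.33
lux,fat,pm,4.68,0.80,695.33,239.95
lux,fat,daily,4.49,0.71,1232.80,404.26
lux,sfa,am,2.91,0.59,364.69,126.28
lux,sfa,pm,3.14,0.59,465.74,159.42
lux,sfa,daily,3.03,0.53,830.43,268.59
lux,mufa,am,1.18,0.29,148.79,61.37
lux,mufa,pm,1.33,0.30,198.17,85.18
lux,mufa,daily,1.26,0.27,346.97,139.58
lux,ufa,am,1.40,0.32,176.17,70.56
lux,ufa,pm,1.56,0.34,233.58,97.09
lux,ufa,daily,1.49,0.30,409.75,159.88
lux,scfa,am,0.40,0.08,51.00,18.47
lux,scfa,pm,0.44,0.08,65.16,23.18
lux,scfa,daily,0.42,0.07,116.16,39.48
lux,mcfa,am,2.30,0.47,288.14,98.17
lux,mcfa,pm,2.47,0.47,365.12,121.71
lux,mcfa,daily,2.39,0.42,653.33,206.66
lux,lcfa,am,1.66,0.41,209.24,87.77
lux,lcfa,pm,1.86,0.44,278.76,122.40
lux,lcfa,daily,1.77,0.39,488.00,200.03
lux,c18_1_cis9,am,0.81,0.23,102.13,46.85
lux,c18_1_cis9,pm,0.91,0.24,136.21,65.34
lux,c18_1_cis9,daily,0.86,0.22,238.35,107.11
wal,milk,am,,,11.41,4.27
wal,milk,pm,,,12.70,4.63
wal,milk,daily,,,24.11,8.64
wal,fat,am,4.00,0.70,448.07,166.73
wal,fat,pm,4.47,0.79,558.72,204.05
wal,fat,daily,4.25,0.75,1006.79,360.00
wal,sfa,am,2.78,0.56,311.57,119.42
wal,sfa,pm,3.00,0.60,375.79,142.26
wal,sfa,daily,2.90,0.58,687.55,254.50
wal,mufa,am,1.06,0.24,117.76,48.00
wal,mufa,pm,1.27,0.29,157.73,62.68
wal,mufa,daily,1.17,0.27,275.49,107.92
wal,ufa,am,1.20,0.26,134.10,54.00
wal,ufa,pm,1.44,0.32,179.10,70.40
wal,ufa,daily,1.33,0.29,313.10,121.30
wal,scfa,am,0.36,0.08,40.79,17.00
wal,scfa,pm,0.38,0.08,48.52,19.90
wal,scfa,daily,0.37,0.08,89.31,36.03
wal,mcfa,am,2.18,0.49,243.85,94.77
wal,mcfa,pm,2.36,0.53,294.22,113.42
wal,mcfa,daily,2.27,0.51,538.08,202.61
wal,lcfa,am,1.46,0.35,163.50,68.96
wal,lcfa,pm,1.73,0.41,215.80,88.64
wal,lcfa,daily,1.60,0.38,379.30,153.91
wal,c18_1_cis9,am,0.75,0.20,83.99,36.72
wal,c18_1_cis9,pm,0.89,0.23,110.90,47.33
wal,c18_1_cis9,daily,0.83,0.21,194.89,82.20
"""

#: relative slack allowed for identities among independently rounded
#: printed values (each figure is printed to 2 decimals)
_PRINT_ROUNDING_RTOL = 5e-4


def reference_stats() -> pd.DataFrame:
    """The published mean/SD tables as a tidy DataFrame."""
    return pd.read_csv(io.StringIO(_REFERENCE_CSV))


def _lookup(df: pd.DataFrame, dataset: str, trait: str, session: str) -> pd.Series:
    row = df[(df.dataset == dataset) & (df.trait == trait) & (df.session == session)]
    assert len(row) == 1
    return row.iloc[0]


def fixture_checks() -> pd.DataFrame:
    """Recompute the arithmetic identities among the published statistics.

    Per dataset and trait, the AM and PM mean yields must sum to the daily
    mean yield (the daily figure is defined as that sum); and for the
    calibration and Walloon populations the saturated share of fat content
    (SFA daily mean over fat daily mean) must reproduce the quoted shares
    of 65.9% and 68.2%.  Each row reports the computed value, the printed
    reference, and a pass flag at print-precision tolerance.
    """
    df = reference_stats()
    rows = []
    for ds in DATASETS:
        for trait in df.trait.unique():
            am = _lookup(df, ds, trait, "am")["yield_mean"]
            pm = _lookup(df, ds, trait, "pm")["yield_mean"]
            daily = _lookup(df, ds, trait, "daily")["yield_mean"]
            computed = am + pm
            ok = abs(computed - daily) <= _PRINT_ROUNDING_RTOL * abs(daily)
            rows.append({
                "check": f"{ds}:{trait}:daily_yield_is_am_plus_pm",
                "computed": round(computed, 2),
                "reference": daily,
                "passed": bool(ok),
            })
    for ds, quoted in (("calibration", 65.9), ("wal", 68.2)):
        sfa = _lookup(df, ds, "sfa", "daily")["content_mean"]
        fat = _lookup(df, ds, "fat", "daily")["content_mean"]
        share = 100.0 * sfa / fat
        rows.append({
            "check": f"{ds}:sfa_share_of_fat_percent",
            "computed": round(share, 1),
            "reference": quoted,
            "passed": bool(round(share, 1) == quoted),
        })
    out = pd.DataFrame(rows)
    assert not out.computed.isna().any()
    return out
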