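"""Expected AM/PM phenotypes from 50/50 mixed samples.

A composite sample made of equal parts morning (AM) and evening (PM) milk
obeys the mixing identity

    content_5050 = 0.5 * content_AM + 0.5 * content_PM

which fixes only the mid-point of the two unobserved session contents.
The missing between-session contrast is borrowed from alternate-scheme
(T) records, where one milking per cow *is* observed: for each trait and
session, a through-origin regression of session trait yield (g) on session
milk yield (kg) gives a slope ``b`` — grams of the trait carried per kg of
milk at that session.  ``b/10`` is then the milk-volume-weighted typical
content (g/dL) of that session, and the difference between the AM and PM
implied contents is the population-level session contrast.

``expected_split`` combines the two sources.  The default ("shift")
combination adds half of the T-predicted AM-PM content difference to the
mixed content for the AM side and subtracts it for the PM side — the
unique linear rule that uses only the mixed observation and the
``b x milk`` expectations, preserves the mixing identity exactly, and
reproduces the predicted between-session contrast.  A "ratio" alternative
allocates the daily trait mass in proportion to the predicted session
yields ``b_s x milk_s`` instead, again constrained to the mixing identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import CONTENT_TRAITS, DL_PER_KG_MILK

__all__ = ["BCoefficients", "estimate_b", "estimate_b_all", "expected_split",
           "daily_yield"]

log = logging.getLogger(__name__)

#: smallest admissible expected content, g/dL
CONTENT_FLOOR = 0.001

SESSIONS = ("am", "pm")


@dataclass(frozen=True)
class BCoefficients:
    """Through-origin slopes of session trait yield on session milk yield.

    ``slope[(trait, session)]`` is in g of trait per kg of milk; dividing
    by 10 gives the implied session content in g/dL.
    """

    slope: dict[tuple[str, str], float]
    n_records: dict[tuple[str, str], int]
    residual_sd: dict[tuple[str, str], float]

    def implied_content(self, trait: str, session: str) -> float:
        """Implied typical content (g/dL) of the session."""
        return self.slope[(trait, session)] / DL_PER_KG_MILK

    def content_contrast(self, trait: str) -> float:
        """Implied AM minus PM content difference (g/dL)."""
        return self.implied_content(trait, "am") - self.implied_content(trait, "pm")


def estimate_b(
    t_records: pd.DataFrame, trait: str, session: str
) -> tuple[float, dict]:
    """Slope of trait yield (g) on milk yield (kg) for one session.

    Uses alternate-scheme records of the given session.  The regression is
    through the origin (no milk, no trait mass), so
    ``b = sum(m*y) / sum(m^2)`` with ``y = content * milk * 10``.

    Returns ``(b, diagnostics)`` where diagnostics carry ``n`` and the
    residual SD of the yield about the fitted line.
    """
    if trait not in CONTENT_TRAITS:
        raise KeyError(f"trait {trait!r} has no content; choose from {CONTENT_TRAITS}")
    if session not in SESSIONS:
        raise ValueError(f"session must be 'am' or 'pm', got {session!r}")
    sub = t_records.loc[t_records["session"] == session]
    if len(sub) < 2:
        raise ValueError(
            f"need >= 2 records of session {session!r} to estimate b, got {len(sub)}"
        )
    m = sub["milk"].to_numpy(dtype=float)
    if (m <= 0).any():
        raise ValueError("milk yields must be positive")
    y = sub[f"content_{trait}"].to_numpy(dtype=float) * m * DL_PER_KG_MILK
    denom = float(np.sum(m * m))
    if denom == 0:
        raise ValueError("sum of squared milk yields is zero")
    b = float(np.sum(m * y) / denom)
    resid = y - b * m
    diag = {"n": int(len(sub)), "residual_sd": float(np.std(resid, ddof=1))}
    return b, diag


def estimate_b_all(
    t_records: pd.DataFrame, traits: tuple[str, ...] = CONTENT_TRAITS
) -> BCoefficients:
    """Estimate b for every trait x session present in the catalogue."""
    slope, n_rec, rsd = {}, {}, {}
    for t in traits:
        for s in SESSIONS:
            b, diag = estimate_b(t_records, t, s)
            slope[(t, s)] = b
            n_rec[(t, s)] = diag["n"]
            rsd[(t, s)] = diag["residual_sd"]
    return BCoefficients(slope=slope, n_records=n_rec, residual_sd=rsd)


def _clip_preserving_midpoint(
    c_am: np.ndarray, c_pm: np.ndarray, c_mix: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Floor negative contents while keeping 0.5*(am+pm) = mix exact."""
    n_clipped = 0
    low_am = c_am < CONTENT_FLOOR
    if low_am.any():
        n_clipped += int(low_am.sum())
        c_am = np.where(low_am, CONTENT_FLOOR, c_am)
        c_pm = np.where(low_am, 2.0 * c_mix - CONTENT_FLOOR, c_pm)
    low_pm = c_pm < CONTENT_FLOOR
    if low_pm.any():
        n_clipped += int(low_pm.sum())
        c_pm = np.where(low_pm, CONTENT_FLOOR, c_pm)
        c_am = np.where(low_pm, 2.0 * c_mix - CONTENT_FLOOR, c_am)
    return c_am, c_pm, n_clipped


def expected_split(
    s_records: pd.DataFrame,
    b: BCoefficients,
    traits: tuple[str, ...] = CONTENT_TRAITS,
    strategy: str = "shift",
) -> pd.DataFrame:
    """Expected per-session contents and yields for mixed-scheme records.

    Parameters
    ----------
    s_records
        Mixed 50/50 records with ``milk_am``, ``milk_pm``, ``milk_daily``
        and ``content_5050_<trait>`` columns.
    b
        Slopes estimated from alternate-scheme data (``estimate_b_all``).
    strategy
        ``"shift"`` (default): session content = mixed content +/- half the
        implied AM-PM content contrast.  ``"ratio"``: allocate the daily
        trait mass by the predicted session-yield ratio
        ``b_AM*milk_AM : b_PM*milk_PM``, rescaled so the mixing identity
        holds exactly.

    Returns a table with, per trait, expected ``content_am/pm`` (g/dL),
    ``yield_am/pm`` and ``yield_daily`` (g), alongside the milk columns.
    Expected contents are floored at a small positive value with the
    partner session re-adjusted, so the mixing identity survives clipping.
    """
    if strategy not in ("shift", "ratio"):
        raise ValueError(f"unknown strategy {strategy!r}")
    m_am = s_records["milk_am"].to_numpy(dtype=float)
    m_pm = s_records["milk_pm"].to_numpy(dtype=float)
    if (m_am <= 0).any() or (m_pm <= 0).any():
        raise ValueError("milk yields must be positive to split mixed records")

    out = s_records[[c for c in ("cow_id", "herd_id", "visit", "parity", "dim",
                                 "month") if c in s_records.columns]].copy()
    out["milk_am"] = m_am
    out["milk_pm"] = m_pm
    out["milk_daily"] = m_am + m_pm

    total_clipped = 0
    for t in traits:
        c_mix = s_records[f"content_5050_{t}"].to_numpy(dtype=float)
        if strategy == "shift":
            d = b.content_contrast(t)  # q_am - q_pm, g/dL
            c_am = c_mix + 0.5 * d
            c_pm = c_mix - 0.5 * d
        else:
            # predicted session yields set the allocation ratio; solve for
            # the PM content from 0.5*(c_am + c_pm) = c_mix
            r = (b.slope[(t, "am")] * m_am) / (b.slope[(t, "pm")] * m_pm)
            c_pm = 2.0 * c_mix / (r * m_pm / m_am + 1.0)
            c_am = 2.0 * c_mix - c_pm
        c_am, c_pm, n_clip = _clip_preserving_midpoint(c_am, c_pm, c_mix)
        total_clipped += n_clip
        out[f"content_am_{t}"] = c_am
        out[f"content_pm_{t}"] = c_pm
        out[f"yield_am_{t}"] = c_am * m_am * DL_PER_KG_MILK
        out[f"yield_pm_{t}"] = c_pm * m_pm * DL_PER_KG_MILK
        out[f"yield_daily_{t}"] = out[f"yield_am_{t}"] + out[f"yield_pm_{t}"]

    frac = total_clipped / max(1, len(s_records) * len(traits))
    if frac > 0.01:
        log.warning(
            "content floor applied to %.1f%% of record-traits; "
            "the implied session contrasts may be too large for these data",
            100 * frac,
        )
    return out


def daily_yield(split: pd.DataFrame, trait: str) -> pd.Series:
    """Expected daily yield: the sum of the two session yields.

    In g/day for content traits; for milk, kg/day (the sum of the two
    milk weights).
    """
    if trait == "milk":
        return split["milk_am"] + split["milk_pm"]
    return split[f"yield_am_{trait}"] + split[f"yield_pm_{trait}"]
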