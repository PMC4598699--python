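"""Synthetic test-day herds with known AM/PM ground truth.

Real milk-recording programmes rarely observe both milkings of the same
cow on the same day, which is exactly why the decomposition and modelling
machinery in this package exists.  The generator here produces complete
ground truth — both milkings' yields and contents for every cow test day —
and then degrades it into the three observation schemes found in routine
recording:

* ``make_s_dataset`` — the 50/50 mixed-sample scheme: one composite sample
  per cow made of equal parts AM and PM milk, plus both milk weights;
* ``make_t_dataset`` — the alternate scheme: one milking observed per
  visit, alternating AM/PM between visits;
* ``make_validation_dataset`` — both milkings fully observed (the kind of
  dedicated sampling campaign used to validate prediction equations).

The mechanism generating a cow test day:

1. daily milk follows a Wood lactation curve ``a * DIM^b * exp(-c*DIM)``
   scaled per parity class, with multiplicative herd and cow effects;
2. the milk at a milking is the daily total times the share of the 24 h
   day occupied by the interval preceding that milking, plus noise — the
   milking after the longer interval carries more milk;
3. fat content at a milking decreases linearly with that milking's milk
   yield (the dilution effect), so the bigger milking is the thinner one;
4. fatty-acid group contents are mean fractions of fat content, with a
   seasonal sinusoid shifting fat from the saturated to the unsaturated
   (and from medium- to long-chain) groups in summer months, plus noise.
   SFA + UFA and SCFA + MCFA + LCFA reconstruct total fat by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .traits import CONTENT_TRAITS, DL_PER_KG_MILK

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "simulate_herds",
    "make_s_dataset",
    "make_t_dataset",
    "make_validation_dataset",
    "apply_outlier_filter",
]

PARITY_CLASSES = (1, 2, 3)  # 3 encodes "third or later lactation"

#: minimum simulated content, g/dL
_CONTENT_FLOOR = 0.01
_RESAMPLE_CAP = 10


class SimulationError(RuntimeError):
    """Raised when the generator cannot produce physical records."""


def _default_wood_params() -> dict[int, tuple[float, float, float]]:
    # (scale kg, rise exponent, decay per day); higher parities peak higher
    return {
        1: (15.0, 0.20, 0.0030),
        2: (17.5, 0.20, 0.0035),
        3: (19.0, 0.20, 0.0038),
    }


def _default_fa_fractions() -> dict[str, float]:
    # mean share of total fat content; SFA+UFA = 1, SCFA+MCFA+LCFA = 1,
    # MUFA within UFA, C18:1 cis-9 within MUFA
    return {
        "sfa": 0.66,
        "ufa": 0.34,
        "mufa": 0.29,
        "scfa": 0.09,
        "mcfa": 0.51,
        "lcfa": 0.40,
        "c18_1_cis9": 0.19,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic herd generator.

    Defaults give a desk-scale population (40 herds x 30 cows x 8 monthly
    visits, ~9,600 cow test days) calibrated to the magnitudes routine
    Holstein milk recording reports: mean daily yield near 26 kg with a
    coefficient of variation near 30%, mean fat content near 4.4 g/dL with
    SD near 0.75, an AM share of daily milk near 48% (11.5 h before the
    morning milking), and between-session content correlations well below
    one.
    """

    n_herds: int = 40
    cows_per_herd: int = 30
    test_days_per_cow: int = 8
    seed: int = 2024
    #: per-parity Wood curve (scale, rise, decay)
    lactation_curve_params: dict[int, tuple[float, float, float]] = field(
        default_factory=_default_wood_params
    )
    #: hours preceding the AM milking ~ Normal(mean, sd), clipped to [4, 20]
    mi_hours_mean_sd: tuple[float, float] = (11.5, 1.0)
    #: fat content change (g/dL) per extra kg of milk at a milking (negative)
    dilution_slope: float = -0.06
    #: seasonal swing (g/dL) moved between saturated and unsaturated fat
    season_amplitude: float = 0.05
    #: mean share of each FA group in total fat content
    fa_fraction_of_fat: dict[str, float] = field(default_factory=_default_fa_fractions)
    noise_sd_content: float = 0.45
    noise_sd_milk: float = 0.8
    #: population mean fat content, g/dL
    fat_mean: float = 4.4
    #: SD of the multiplicative cow milk-level effect
    cow_effect_sd: float = 0.25
    #: SD of the multiplicative herd milk-level effect
    herd_effect_sd: float = 0.10
    #: SD of the additive per-cow fat-level effect, g/dL
    cow_fat_sd: float = 0.60

    def __post_init__(self) -> None:
        for name in ("n_herds", "cows_per_herd", "test_days_per_cow"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("noise_sd_content", "noise_sd_milk", "cow_effect_sd",
                     "herd_effect_sd", "cow_fat_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mi_hours_mean_sd[1] < 0:
            raise ValueError("milking-interval SD must be >= 0")
        if not 0 < self.mi_hours_mean_sd[0] < 24:
            raise ValueError("mean AM milking interval must lie in (0, 24) h")
        fr = self.fa_fraction_of_fat
        missing = set(_default_fa_fractions()) - set(fr)
        if missing:
            raise ValueError(f"fa_fraction_of_fat missing traits: {sorted(missing)}")
        for t, f in fr.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"FA fraction for {t!r} must lie in (0, 1), got {f}")
        if abs(fr["sfa"] + fr["ufa"] - 1.0) > 1e-9:
            raise ValueError("mean SFA and UFA fractions of fat must sum to 1")
        if abs(fr["scfa"] + fr["mcfa"] + fr["lcfa"] - 1.0) > 1e-9:
            raise ValueError("mean SCFA, MCFA and LCFA fractions of fat must sum to 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _wood(dim: np.ndarray, params: np.ndarray) -> np.ndarray:
    a, b, c = params[:, 0], params[:, 1], params[:, 2]
    return a * dim**b * np.exp(-c * dim)


def _resample_positive(draw, values: np.ndarray, what: str) -> np.ndarray:
    """Redraw entries of ``values`` that are <= 0, up to a retry cap."""
    for _ in range(_RESAMPLE_CAP):
        bad = values <= 0
        if not bad.any():
            return values
        values = np.where(bad, draw(int(bad.sum())), values)
    if (values <= 0).any():
        raise SimulationError(
            f"could not draw positive {what} after {_RESAMPLE_CAP} retries; "
            "check noise/scale parameters"
        )
    return values


def simulate_herds(config: SimulationConfig) -> pd.DataFrame:
    """Generate the ground-truth table of cow test days.

    Returns one row per cow per visit with herd/cow identifiers, parity
    class (1, 2, 3+), days in milk, calendar month, the two milking
    intervals (``mi_am`` + ``mi_pm`` = 24 h), both milk weights (kg) and
    both milkings' contents (g/dL) for the eight content traits.
    Deterministic for a given config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n_cows = config.n_herds * config.cows_per_herd
    n_days = config.test_days_per_cow
    n = n_cows * n_days

    herd_of_cow = np.repeat(np.arange(config.n_herds), config.cows_per_herd)
    parity = rng.choice(PARITY_CLASSES, size=n_cows, p=(0.36, 0.28, 0.36))
    cow_eff = np.exp(rng.normal(0.0, config.cow_effect_sd, size=n_cows))
    herd_eff = np.exp(rng.normal(0.0, config.herd_effect_sd, size=config.n_herds))
    cow_fat = rng.normal(0.0, config.cow_fat_sd, size=n_cows)

    # visits are ~monthly; first visit between DIM 5 and 155 keeps DIM <= 365
    max_start = max(6, 365 - 30 * (n_days - 1) - 5)
    dim0 = rng.integers(5, max_start, size=n_cows)
    start_month = rng.integers(1, 13, size=n_cows)

    visit = np.tile(np.arange(n_days), n_cows)
    cow_idx = np.repeat(np.arange(n_cows), n_days)

    dim = dim0[cow_idx] + 30 * visit
    month = (start_month[cow_idx] - 1 + visit) % 12 + 1

    wood_par = np.array(
        [config.lactation_curve_params[p] for p in PARITY_CLASSES], dtype=float
    )
    par_idx = np.searchsorted(np.array(PARITY_CLASSES), parity[cow_idx])
    daily_milk = (
        _wood(dim.astype(float), wood_par[par_idx])
        * cow_eff[cow_idx]
        * herd_eff[herd_of_cow[cow_idx]]
    )
    daily_milk = _resample_positive(
        lambda k: rng.uniform(5.0, 15.0, size=k), daily_milk, "daily milk"
    )

    mi_mean, mi_sd = config.mi_hours_mean_sd
    mi_am = np.clip(rng.normal(mi_mean, mi_sd, size=n), 4.0, 20.0)
    mi_pm = 24.0 - mi_am

    milk_am = daily_milk * mi_am / 24.0 + rng.normal(0.0, config.noise_sd_milk, size=n)
    # clamp the split so both milkings stay positive, then resample leftovers
    for _ in range(_RESAMPLE_CAP):
        bad = (milk_am <= 0) | (milk_am >= daily_milk)
        if not bad.any():
            break
        redraw = daily_milk * mi_am / 24.0 + rng.normal(
            0.0, config.noise_sd_milk, size=n
        )
        milk_am = np.where(bad, redraw, milk_am)
    else:
        bad = (milk_am <= 0) | (milk_am >= daily_milk)
        if bad.any():
            raise SimulationError(
                "could not split daily milk into two positive milkings; "
                "noise_sd_milk is too large for the smallest daily yields"
            )
    milk_pm = daily_milk - milk_am

    # per-day fat level: cow effect plus a mild late-lactation rise
    fat_base = (
        config.fat_mean + cow_fat[cow_idx] + 0.0015 * (dim - 150.0)
    )
    eps_am = rng.normal(0.0, config.noise_sd_content, size=n)
    eps_pm = rng.normal(0.0, config.noise_sd_content, size=n)
    half = daily_milk / 2.0
    fat_am = fat_base + config.dilution_slope * (milk_am - half) + eps_am
    fat_pm = fat_base + config.dilution_slope * (milk_pm - half) + eps_pm
    fat_am = np.maximum(fat_am, 10 * _CONTENT_FLOOR)
    fat_pm = np.maximum(fat_pm, 10 * _CONTENT_FLOOR)

    out = {
        "cow_id": cow_idx,
        "herd_id": herd_of_cow[cow_idx],
        "visit": visit,
        "parity": parity[cow_idx],
        "dim": dim,
        "month": month,
        "mi_am": mi_am,
        "mi_pm": mi_pm,
        "milk_am": milk_am,
        "milk_pm": milk_pm,
        "content_am_fat": fat_am,
        "content_pm_fat": fat_pm,
    }

    fr = config.fa_fraction_of_fat
    amp = config.season_amplitude
    # unsaturated / long-chain fractions peak mid-summer (grazing season)
    season = np.sin(2.0 * math.pi * (month - 4) / 12.0)
    for sess, fat_s in (("am", fat_am), ("pm", fat_pm)):
        def eta(scale: float):
            return rng.normal(0.0, config.noise_sd_content * scale, size=n)

        sfa = fat_s * fr["sfa"] - amp * season + eta(fr["sfa"] * 0.5)
        sfa = np.clip(sfa, _CONTENT_FLOOR, fat_s - _CONTENT_FLOOR)
        ufa = fat_s - sfa
        mufa = ufa * (fr["mufa"] / fr["ufa"]) + eta(fr["mufa"] * 0.3)
        mufa = np.clip(mufa, _CONTENT_FLOOR, ufa)
        c18 = mufa * (fr["c18_1_cis9"] / fr["mufa"]) + eta(fr["c18_1_cis9"] * 0.3)
        c18 = np.clip(c18, _CONTENT_FLOOR, mufa)
        scfa = fat_s * fr["scfa"] + eta(fr["scfa"] * 0.5)
        scfa = np.clip(scfa, _CONTENT_FLOOR, fat_s * 0.5)
        lcfa = fat_s * fr["lcfa"] + amp * season + eta(fr["lcfa"] * 0.5)
        lcfa = np.clip(lcfa, _CONTENT_FLOOR, fat_s - scfa - _CONTENT_FLOOR)
        mcfa = fat_s - scfa - lcfa
        out[f"content_{sess}_sfa"] = sfa
        out[f"content_{sess}_ufa"] = ufa
        out[f"content_{sess}_mufa"] = mufa
        out[f"content_{sess}_c18_1_cis9"] = c18
        out[f"content_{sess}_scfa"] = scfa
        out[f"content_{sess}_lcfa"] = lcfa
        out[f"content_{sess}_mcfa"] = mcfa

    cols = ["cow_id", "herd_id", "visit", "parity", "dim", "month",
            "mi_am", "mi_pm", "milk_am", "milk_pm"]
    cols += [f"content_{s}_{t}" for t in CONTENT_TRAITS for s in ("am", "pm")]
    return pd.DataFrame(out)[cols]


def make_s_dataset(truth: pd.DataFrame) -> pd.DataFrame:
    """Mixed 50/50 scheme: composite content plus both milk weights.

    The composite sample contains equal volumes of AM and PM milk, so its
    content is the plain average of the two milkings' contents.
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    out = truth[["cow_id", "herd_id", "visit", "parity", "dim", "month",
                 "milk_am", "milk_pm"]].copy()
    out["milk_daily"] = truth["milk_am"] + truth["milk_pm"]
    for t in CONTENT_TRAITS:
        out[f"content_5050_{t}"] = (
            0.5 * truth[f"content_am_{t}"] + 0.5 * truth[f"content_pm_{t}"]
        )
    return out


def make_t_dataset(truth: pd.DataFrame, scheme="alternate") -> pd.DataFrame:
    """Alternate scheme: one milking observed per herd visit.

    With the default rule a herd's first visit records every cow at the AM
    milking, the second at the PM milking, and so on.  ``scheme`` may be a
    callable ``(herd_id, visit) -> "am" | "pm"`` implementing another rule.
    """
    if truth.empty:
        return pd.DataFrame(
            columns=["cow_id", "herd_id", "visit", "parity", "dim", "month",
                     "session", "milk"]
            + [f"content_{t}" for t in CONTENT_TRAITS]
        )
    if scheme == "alternate":
        session = np.where(truth["visit"] % 2 == 0, "am", "pm")
    elif callable(scheme):
        session = np.array(
            [scheme(h, v) for h, v in zip(truth["herd_id"], truth["visit"])]
        )
        if not np.isin(session, ("am", "pm")).all():
            raise ValueError("scheme callable must return 'am' or 'pm'")
    else:
        raise ValueError(f"unknown alternation scheme {scheme!r}")

    out = truth[["cow_id", "herd_id", "visit", "parity", "dim", "month"]].copy()
    out["session"] = session
    is_am = session == "am"
    out["milk"] = np.where(is_am, truth["milk_am"], truth["milk_pm"])
    for t in CONTENT_TRAITS:
        out[f"content_{t}"] = np.where(
            is_am, truth[f"content_am_{t}"], truth[f"content_pm_{t}"]
        )
    return out


def make_validation_dataset(truth: pd.DataFrame) -> pd.DataFrame:
    """Both milkings observed: yields and contents per session plus daily sums."""
    if truth.empty:
        raise ValueError("truth table is empty")
    out = truth[["cow_id", "herd_id", "visit", "parity", "dim", "month",
                 "milk_am", "milk_pm"]].copy()
    out["milk_daily"] = truth["milk_am"] + truth["milk_pm"]
    for t in CONTENT_TRAITS:
        c_am = truth[f"content_am_{t}"]
        c_pm = truth[f"content_pm_{t}"]
        out[f"content_am_{t}"] = c_am
        out[f"content_pm_{t}"] = c_pm
        out[f"yield_am_{t}"] = c_am * truth["milk_am"] * DL_PER_KG_MILK
        out[f"yield_pm_{t}"] = c_pm * truth["milk_pm"] * DL_PER_KG_MILK
        out[f"yield_daily_{t}"] = out[f"yield_am_{t}"] + out[f"yield_pm_{t}"]
    return out


def apply_outlier_filter(
    records: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, int]:
    """Drop records outside mean +/- 3 SD on any of the given columns.

    Means and sample SDs are computed once, on the full input.  A column
    with zero SD imposes no restriction (the +/- 3 SD rule is vacuous when
    there is no variance).  Returns the kept records and the removal count.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to compute an SD filter")
    keep = np.ones(len(records), dtype=bool)
    for col in columns:
        x = records[col].to_numpy(dtype=float)
        mu = x.mean()
        sd = x.std(ddof=1)
        if sd == 0:
            continue
        keep &= (x >= mu - 3 * sd) & (x <= mu + 3 * sd)
    kept = records.loc[keep]
    return kept, int((~keep).sum())
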