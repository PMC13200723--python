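"""Growth-trial arithmetic: specific growth rate, feed conversion ratio,
Fulton's condition factor, ration sizing and tidy per-week trial tables.

The specific growth rate is the instantaneous (log-mass) rate
g = (ln M2 − ln M1)/Δt, conventionally reported as G = 100·g in % day⁻¹.
FCR = feed intake / mass gain (both in mg).  Fulton's condition factor is
K = 100·M/L³ with M in g and L in cm.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SGRResult",
    "FCRResult",
    "sgr",
    "fcr",
    "condition_factor",
    "ration_mass",
    "growth_table",
]


class SGRResult(NamedTuple):
    g: float            # instantaneous growth rate, day⁻¹
    pct_per_day: float  # G = 100·g, % day⁻¹


def sgr(m1: float, m2: float, dt_days: float) -> SGRResult:
    """Specific growth rate from start/end masses over dt_days."""
    if m1 <= 0 or m2 <= 0:
        raise ValueError("masses must be positive")
    if dt_days <= 0:
        raise ValueError("dt_days must be positive")
    g = (math.log(m2) - math.log(m1)) / dt_days
    return SGRResult(g, 100.0 * g)


class FCRResult(NamedTuple):
    fcr: float
    reason: str  # "no growth" when gain <= 0 (fcr is NaN, not an error)


def fcr(feed_mg: float, gain_mg: float) -> FCRResult:
    """Feed conversion ratio = feed intake / mass gain (mg/mg).

    A non-positive gain yields a flagged NaN rather than an exception: the
    ratio is undefined over an interval without growth.
    """
    if feed_mg < 0:
        raise ValueError("feed_mg must be non-negative")
    if gain_mg <= 0:
        return FCRResult(float("nan"), "no growth")
    return FCRResult(feed_mg / gain_mg, "")


def condition_factor(mass: float, length: float) -> float:
    """Fulton's K = 100·mass/length³ (mass in g, length in cm)."""
    if mass <= 0 or length <= 0:
        raise ValueError("mass and length must be positive")
    return 100.0 * mass / length**3


def ration_mass(mass: float, ration_fraction: float) -> float:
    """Daily feed mass (g) for a body-mass-proportional ration."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if not 0.0 < ration_fraction < 1.0:
        raise ValueError("ration_fraction must be in (0, 1)")
    return mass * ration_fraction


def growth_table(records: pd.DataFrame, dt_days: float = 7.0) -> pd.DataFrame:
    """Per-animal weekly growth metrics from a long-format trial table.

    ``records`` needs columns (animal_id, week, mass_g) and optionally
    genotype, period, feed_mg, length_cm.  Each consecutive week pair
    (w → w+1) yields one row with g, sgr_pct_per_day, fcr (if feed_mg for
    the interval is present on the ending week's row) and k (if length_cm
    is present).  Weigh intervals default to 7 days; pass ``dt_days`` to
    override uniformly.
    """
    out = []
    for animal, grp in records.groupby("animal_id", sort=False):
        grp = grp.sort_values("week")
        for prev, cur in zip(grp.iloc[:-1].itertuples(),
                             grp.iloc[1:].itertuples()):
            rate = sgr(prev.mass_g, cur.mass_g, dt_days)
            gain_mg = (cur.mass_g - prev.mass_g) * 1000.0
            feed = getattr(cur, "feed_mg", np.nan)
            ratio = fcr(feed, gain_mg) if np.isfinite(feed) else FCRResult(
                float("nan"), "no feed data")
            length = getattr(cur, "length_cm", np.nan)
            k = (condition_factor(cur.mass_g, length)
                 if np.isfinite(length) else np.nan)
            out.append({
                "animal_id": animal,
                "genotype": getattr(cur, "genotype", ""),
                "week": cur.week,
                "period": getattr(cur, "period", ""),
                "mass_start_g": prev.mass_g,
                "mass_end_g": cur.mass_g,
                "g_per_day": rate.g,
                "sgr_pct_per_day": rate.pct_per_day,
                "fcr": ratio.fcr,
                "fcr_flag": ratio.reason,
                "k": k,
            })
    return pd.DataFrame(out)
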