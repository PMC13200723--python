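"""Static-chamber nitrogen and acid-base flux budgets.

A fed (or fasted) fish sits in a small aerated static chamber and the water
is sampled repeatedly.  The net mass-specific flux of an analyte X (total
ammonia, TAN, in µmol l⁻¹, or titratable alkalinity, TAlk, in µEq l⁻¹)
over a sampling interval is

    J_X = ([X]_f − [X]_i) · V / (M · t)

with V the water volume (l), M the fish mass (kg) and t the interval
duration (h).  Positive J means excretion into the water.  The net
acid-base flux is J_TAlk − J_TAmm (µEq kg⁻¹ h⁻¹): negative values indicate
net base uptake (i.e. acid excretion) and positive values net base
excretion.

The module also covers NH3/NH4+ speciation (apparent pK' model), the
cumulative post-prandial ammonia budget relative to a baseline, and a
stoichiometric model of the direct oxygen cost of gastric acid secretion
(the proton pump moves 1 H+ per ATP; published H+:O2 ratios bracket the
cost).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import pandas as pd

__all__ = [
    "FluxInterval",
    "TitrationRecord",
    "SpeciationParams",
    "AcidCostModel",
    "DEFAULT_SPECIATION_23C",
    "net_flux",
    "titratable_alkalinity",
    "net_acid_base",
    "cumulative_tan",
    "meal_tan_fraction",
    "nh3_speciation",
    "acid_cost",
    "interval_fluxes",
]


@dataclass(frozen=True)
class FluxInterval:
    """One chamber sampling interval for a single analyte.

    Concentrations are per-litre amounts ([X]_i initial, [X]_f final, in
    µmol l⁻¹ for TAN or µEq l⁻¹ for TAlk); volume in l, mass in kg,
    duration in h.  ``start_h`` (optional) anchors the interval on the
    experiment clock for contiguity checks.
    """

    animal_id: str
    analyte: str
    conc_initial: float
    conc_final: float
    volume: float
    mass: float
    duration: float
    start_h: float | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def end_h(self) -> float | None:
        return None if self.start_h is None else self.start_h + self.duration


def net_flux(interval: FluxInterval) -> float:
    """Net mass-specific flux J_X = ([X]_f − [X]_i)·V/(M·t).

    Positive = excretion into the water (accumulation).  Units follow the
    analyte: µmol kg⁻¹ h⁻¹ for TAN, µEq kg⁻¹ h⁻¹ for TAlk.
    """
    if interval.duration <= 0:
        raise ValueError("duration must be positive")
    return ((interval.conc_final - interval.conc_initial) * interval.volume
            / (interval.mass * interval.duration))


@dataclass(frozen=True)
class TitrationRecord:
    """Acid titration of a chamber water sample to the pH 4.0 endpoint.

    The two-stage protocol (automatic titration to pH 4.3 followed by a
    manual finish to pH 4.0) is collapsed into the total titrant volume;
    use :meth:`from_stages` to sum per-stage volumes.  Volumes in litres,
    normality in Eq l⁻¹.
    """

    sample_volume: float
    titrant_normality: float
    titrant_volume: float

    def __post_init__(self) -> None:
        if self.sample_volume <= 0:
            raise ValueError("sample volume must be positive")
        if self.titrant_normality <= 0:
            raise ValueError("titrant normality must be positive")
        if self.titrant_volume < 0:
            raise ValueError("titrant volume must be non-negative")

    @classmethod
    def from_stages(cls, sample_volume: float, titrant_normality: float,
                    stage_volumes: Sequence[float]) -> "TitrationRecord":
        return cls(sample_volume, titrant_normality, float(sum(stage_volumes)))


def titratable_alkalinity(rec: TitrationRecord) -> float:
    """Titratable alkalinity (µEq l⁻¹) of the water sample."""
    return (rec.titrant_volume * rec.titrant_normality
            / rec.sample_volume * 1e6)


def net_acid_base(j_talk: float, j_tamm: float) -> float:
    """Net acid-base flux = J_TAlk − J_TAmm (µEq kg⁻¹ h⁻¹).

    Negative values indicate a net base uptake (i.e. acid excretion) and
    positive values indicate net base excretion.
    """
    return j_talk - j_tamm


def cumulative_tan(fluxes: Sequence[FluxInterval], baseline: float,
                   mass: float | None = None) -> float:
    """Cumulative ammonia excreted above baseline (µmol) over contiguous
    intervals: Σ max(J_TAmm − baseline, 0) · mass · duration.

    ``mass`` defaults to the (common) interval mass.  Raises on overlapping
    intervals when start times are given.
    """
    if not fluxes:
        return 0.0
    if mass is None:
        masses = {iv.mass for iv in fluxes}
        if len(masses) != 1:
            raise ValueError("intervals have differing masses; pass mass")
        mass = masses.pop()
    starts = [iv.start_h for iv in fluxes]
    if all(s is not None for s in starts):
        for prev, cur in zip(fluxes[:-1], fluxes[1:]):
            if cur.start_h < prev.end_h - 1e-9:
                raise ValueError(
                    f"overlapping intervals at t={cur.start_h} h")
    total = 0.0
    for iv in fluxes:
        total += max(net_flux(iv) - baseline, 0.0) * mass * iv.duration
    return total


class MealTanFraction(NamedTuple):
    percent: float
    exceeds_meal: bool  # >100%: catabolic ammonia beyond direct absorption


def meal_tan_fraction(excreted_over_baseline: float,
                      meal_tan: float) -> MealTanFraction:
    """Excreted-above-baseline TAN as a percentage of the meal's ammonia
    content.  May exceed 100% when catabolism adds ammonia beyond what was
    ingested; the flag marks that case."""
    if meal_tan <= 0:
        raise ValueError("meal_tan must be positive")
    pct = 100.0 * excreted_over_baseline / meal_tan
    return MealTanFraction(pct, pct > 100.0)


@dataclass(frozen=True)
class SpeciationParams:
    """Apparent NH4+/NH3 equilibrium parameters.

    pK_prime: apparent pK at the working temperature/ionic strength;
    alpha_nh3: NH3 solubility in µmol l⁻¹ torr⁻¹; ionic_strength in
    mmol l⁻¹ is a documentation field.
    """

    pK_prime: float
    alpha_nh3: float
    ionic_strength: float = 125.0

    def __post_init__(self) -> None:
        if not 7.0 < self.pK_prime < 11.0:
            raise ValueError("pK_prime outside plausible range (7, 11)")
        if self.alpha_nh3 <= 0:
            raise ValueError("alpha_nh3 must be positive")


#: Generic fresh-water values near 23 °C (thermodynamic pK of NH4+ with a
#: modest ionic-strength correction; Henry-law NH3 solubility).  Meant as a
#: documented starting point — override with values matched to your water.
DEFAULT_SPECIATION_23C = SpeciationParams(pK_prime=9.33, alpha_nh3=8.1e4)


class Speciation(NamedTuple):
    nh3: float    # µmol l⁻¹
    p_nh3: float  # torr


def nh3_speciation(tan: float, ph: float,
                   params: SpeciationParams) -> Speciation:
    """Split total ammonia into un-ionised NH3 and its partial pressure.

    nh3 = TAN / (1 + 10^(pK' − pH));  P_NH3 = nh3 / alpha_nh3.
    """
    if tan < 0:
        raise ValueError("tan must be non-negative")
    nh3 = tan / (1.0 + 10.0 ** (params.pK_prime - ph))
    return Speciation(nh3, nh3 / params.alpha_nh3)


@dataclass(frozen=True)
class AcidCostModel:
    """Direct oxygen cost of post-prandial gastric acid secretion.

    The acid load neutralised per g body mass is either supplied directly
    (``acid_load``, µmol H+ g⁻¹) or derived as
    buffer_capacity (µmol H+ (g meal)⁻¹ pH⁻¹) × delta_ph × ration (g g⁻¹).
    ``h_o2_ratio`` (rho) is the H+ secreted per O2 consumed; o2_cost =
    acid_load / rho (µmol O2 g⁻¹) and sda_share expresses it as % of the
    SDA magnitude.
    """

    h_o2_ratio: float
    delta_ph: float | None = None
    buffer_capacity: float | None = None
    ration: float | None = None
    acid_load: float | None = None
    o2_cost: float | None = None
    sda_share: float | None = None


def acid_cost(model: AcidCostModel, sda_magnitude: float) -> AcidCostModel:
    """Complete an :class:`AcidCostModel` against an SDA magnitude
    (µmol O2 g⁻¹): fills acid_load (if derivable), o2_cost and sda_share."""
    if model.h_o2_ratio <= 0:
        raise ValueError("h_o2_ratio must be positive")
    if sda_magnitude <= 0:
        raise ValueError("sda_magnitude must be positive")
    load = model.acid_load
    if load is None:
        if None in (model.buffer_capacity, model.delta_ph, model.ration):
            raise ValueError(
                "need acid_load or (buffer_capacity, delta_ph, ration)")
        load = model.buffer_capacity * model.delta_ph * model.ration
    o2_cost = load / model.h_o2_ratio
    share = 100.0 * o2_cost / sda_magnitude
    return replace(model, acid_load=load, o2_cost=o2_cost, sda_share=share)


def interval_fluxes(samples: pd.DataFrame, volume_l: float, mass_kg: float,
                    animal_id: str = "") -> pd.DataFrame:
    """Tidy per-interval flux table from a water-sample series.

    ``samples`` has columns time_h (increasing) and one or both of
    tan_umol_l / talk_ueq_l.  Returns one row per consecutive interval
    with j_tamm, j_talk and net_acid_base where both analytes are present.
    """
    samples = samples.sort_values("time_h")
    t = samples["time_h"].to_numpy(float)
    rows = []
    for k in range(len(t) - 1):
        row = {"animal_id": animal_id, "start_h": t[k], "end_h": t[k + 1]}
        for analyte, col, key in (("TAN", "tan_umol_l", "j_tamm"),
                                  ("TAlk", "talk_ueq_l", "j_talk")):
            if col in samples.columns:
                iv = FluxInterval(
                    animal_id=animal_id, analyte=analyte,
                    conc_initial=float(samples[col].iloc[k]),
                    conc_final=float(samples[col].iloc[k + 1]),
                    volume=volume_l, mass=mass_kg,
                    duration=t[k + 1] - t[k], start_h=t[k])
                row[key] = net_flux(iv)
        if "j_tamm" in row and "j_talk" in row:
            row["net_acid_base"] = net_acid_base(row["j_talk"],
                                                 row["j_tamm"])
        rows.append(row)
    return pd.DataFrame(rows)
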