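"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator emulates one experimental data stream and returns both the
raw data (in the same in-memory form the analysis stages read) and a truth
record for parameter-recovery testing:

* respirometry traces — a baseline metabolic rate plus a transient
  post-prandial bump with per-cycle measurement noise, optional activity
  spikes and regurgitation;
* static-chamber water samples — piecewise-constant true fluxes integrated
  into chamber concentrations at the standard sampling grid;
* growth trials — exponential mass trajectories with a drug-depression
  window;
* qPCR Ct tables — reference genes constant in expectation, target genes
  shifted by per-gene log2 effects, with per-sample loading offsets.

Every generator is a measurable inverse pair with its pipeline stage in the
noise-free limit, and all outputs are reproducible bit-for-bit under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .respirometry import RespTrace

__all__ = [
    "SimConfig",
    "bump_profile",
    "bump_area",
    "bump_return_time",
    "simulate_resp_trace",
    "simulate_resp_group",
    "simulate_flux_series",
    "simulate_growth",
    "simulate_ct_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators.

    Respirometry group means and the knockout contrasts mirror the study
    this pipeline reconstructs (near-equal SMR, −21.8% magnitude, −11%
    duration); between-animal s.d. values are the study's printed
    s.e.m. × sqrt(n).  Flux sampling follows the 0/3/6/9/24 h grid; the
    growth trial is 3 control + 2 omeprazole + 3 recovery weeks with a
    45.2% growth-rate depression in the drug window and early recovery.
    """

    seed: int = 0
    n_per_group: int = 12

    # --- respirometry ---
    smr_mean_wt: float = 5.3      # µmol O2 g⁻¹ h⁻¹
    smr_mean_ko: float = 5.1
    smr_sd: float = 1.1
    sda_peak_mean: float = 3.03   # wild-type net peak above SMR
    sda_peak_sd: float = 0.5
    sda_duration_mean: float = 15.25  # h, wild-type bump timescale
    sda_duration_sd: float = 1.5
    magnitude_effect: float = -0.218  # knockout magnitude contrast
    duration_effect: float = -0.11    # knockout duration contrast
    cycle_noise_sd: float = 0.25      # µmol O2 g⁻¹ h⁻¹ per-cycle noise
    activity_spike_rate: float = 0.0  # spikes h⁻¹
    spike_o2_noise_sd: float = 3.0    # µmol l⁻¹ within-cycle noise on spikes
    regurgitation_prob: float = 0.0
    regurgitation_duration_h: float = 3.0
    record_h: float = 24.0
    cycle_period_h: float = 0.25      # 10 min measure + 5 min flush
    measure_fraction: float = 2.0 / 3.0
    sample_dt_h: float = 1.0 / 60.0
    o2_start: float = 250.0           # µmol l⁻¹ at each cycle start
    chamber_ml: float = 40.0
    mass_mean_g: float = 0.4
    mass_sd_g: float = 0.04
    bump_beta: float = 4.0            # gamma-shape-2 profile decay rate
    return_fraction: float = 0.10     # "returned to SMR" tolerance for truth

    # --- fluxes ---
    flux_sample_times: tuple = (0.0, 3.0, 6.0, 9.0, 24.0)
    flux_chamber_l: float = 0.05
    flux_mass_kg: float = 4e-4
    tamm_baseline: float = 300.0          # µmol kg⁻¹ h⁻¹
    tamm_postfeed_excess_wt: float = 1000.0
    tamm_postfeed_excess_ko: float = 1000.0 / 3.65
    talk_baseline: float = 0.0            # µEq kg⁻¹ h⁻¹
    talk_postfeed_excess_wt: float = -200.0  # base uptake while fed
    talk_postfeed_excess_ko: float = 50.0
    flux_decay_half_life_h: float = 6.0
    talk_start_ueq_l: float = 1000.0
    flux_conc_noise_sd: float = 0.0       # µmol l⁻¹ (or µEq l⁻¹)

    # --- growth ---
    n_weeks: int = 8
    period_weeks: tuple = (3, 2, 3)       # control, omeprazole, recovery
    base_sgr_pct_per_day: float = 2.36
    drug_depression_fraction: float = 0.452
    depressed_weeks: tuple = (5, 6, 7)    # trial weeks with depressed growth
    start_mass_g: float = 0.10
    start_mass_sd_g: float = 0.03
    growth_ration_fraction: float = 0.03
    mass_noise_cv: float = 0.0            # multiplicative weighing noise

    # --- qPCR ---
    reference_genes: tuple = ("ef1a", "18s", "gapdh")
    reference_base_ct: tuple = (18.0, 10.0, 20.0)
    target_base_ct: dict = field(default_factory=lambda: {"cck": 26.0})
    target_log2_effect: dict = field(default_factory=lambda: {"cck": -1.0})
    qpcr_efficiency: dict = field(default_factory=lambda: {"cck": 95.3})
    ct_noise_sd: float = 0.0
    qpcr_loading_sd: float = 0.3


# ---------------------------------------------------------------------------
# respirometry

def _gamma_curve(x: np.ndarray | float, beta: float) -> np.ndarray | float:
    return x * np.exp(-beta * x)


def bump_profile(x, beta: float = 4.0):
    """Normalised SDA bump shape on [0, 1]: a gamma-density (shape 2)
    profile with its tail value subtracted so support is exactly [0, 1]
    and the maximum is 1.  Values outside [0, 1] (and the tiny negative
    strip near 0 created by the subtraction) are clamped to 0."""
    x = np.asarray(x, dtype=float)
    g1 = _gamma_curve(1.0, beta)
    gm = _gamma_curve(1.0 / beta, beta)
    p = (_gamma_curve(np.clip(x, 0.0, 1.0), beta) - g1) / (gm - g1)
    p = np.where((x < 0.0) | (x > 1.0), 0.0, p)
    return np.maximum(p, 0.0)


def bump_area(peak: float, duration: float, beta: float = 4.0) -> float:
    """Analytic (quadrature) area under the bump, µmol O2 g⁻¹."""
    if duration <= 0 or peak <= 0:
        return 0.0
    val, _ = quad(lambda t: peak * float(bump_profile(t / duration, beta)),
                  0.0, duration, limit=200)
    return val


def bump_return_time(peak: float, duration: float, smr: float,
                     return_fraction: float, beta: float = 4.0) -> float:
    """Time at which the descending bump crosses return_fraction × SMR —
    the operational SDA duration (return to within the tolerance of SMR)."""
    if duration <= 0 or peak <= 0:
        return 0.0
    level = return_fraction * smr / peak
    if level >= 1.0:
        return 0.0
    if level <= 0.0:
        return duration
    xm = 1.0 / beta
    f = lambda x: float(bump_profile(x, beta)) - level
    return duration * brentq(f, xm, 1.0, xtol=1e-12)


def simulate_resp_trace(cfg: SimConfig, animal_id: str = "A1",
                        genotype: str = "wt",
                        rng: np.random.Generator | None = None):
    """Simulate one 24 h intermittent-flow record.

    The true MO2 at each cycle midpoint is SMR + bump (+ cycle noise); O2
    samples within the measure phase are back-computed through the chamber
    mass balance (slope = −MO2·M/V_eff), so `compute_mo2` inverts the
    generator exactly in the noise-free limit.  Returns (RespTrace, truth
    dict); truth records the drawn parameters, the operational duration
    (return to within ``cfg.return_fraction`` of SMR) and the analytic
    bump area.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ko = genotype == "ko"
    smr = max(rng.normal(cfg.smr_mean_ko if ko else cfg.smr_mean_wt,
                         cfg.smr_sd), 0.5)
    peak = max(rng.normal(cfg.sda_peak_mean, cfg.sda_peak_sd), 0.2)
    dur = max(rng.normal(cfg.sda_duration_mean, cfg.sda_duration_sd), 1.0)
    if ko:
        dur *= 1.0 + cfg.duration_effect
        peak *= (1.0 + cfg.magnitude_effect) / (1.0 + cfg.duration_effect)
    regurgitated = rng.random() < cfg.regurgitation_prob
    if regurgitated:
        dur = cfg.regurgitation_duration_h
    mass = max(rng.normal(cfg.mass_mean_g, cfg.mass_sd_g), 0.05)
    fish_ml = mass  # 1 g ml⁻¹
    veff_l = (cfg.chamber_ml - fish_ml) / 1000.0

    n_cycles = int(cfg.record_h / cfg.cycle_period_h)
    measure_len = cfg.measure_fraction * cfg.cycle_period_h
    rel_t = np.arange(0.0, measure_len + cfg.sample_dt_h / 2, cfg.sample_dt_h)

    n_spikes = rng.poisson(cfg.activity_spike_rate * cfg.record_h)
    spike_cycles = set()
    if n_spikes:
        spike_cycles = set(
            (rng.uniform(0.0, cfg.record_h, n_spikes)
             // cfg.cycle_period_h).astype(int))

    frames, truth_mo2 = [], np.empty(n_cycles)
    for c in range(n_cycles):
        t0 = c * cfg.cycle_period_h
        mid = t0 + measure_len / 2.0
        mo2 = smr + peak * float(bump_profile(mid / dur, cfg.bump_beta))
        if cfg.cycle_noise_sd > 0:
            mo2 += rng.normal(0.0, cfg.cycle_noise_sd)
        mo2 = max(mo2, 0.1)
        truth_mo2[c] = mo2
        slope = -mo2 * mass / veff_l
        o2 = cfg.o2_start + slope * rel_t
        if c in spike_cycles:
            o2 = o2 + rng.normal(0.0, cfg.spike_o2_noise_sd, len(rel_t))
        frames.append(pd.DataFrame({
            "time": t0 + rel_t,
            "o2": np.maximum(o2, 0.0),
            "phase": "measure",
            "cycle": c,
        }))
    samples = pd.concat(frames, ignore_index=True)
    trace = RespTrace(animal_id=animal_id, genotype=genotype, mass=mass,
                      chamber_volume=cfg.chamber_ml, fish_volume=fish_ml,
                      samples=samples)
    truth = {
        "animal_id": animal_id,
        "genotype": genotype,
        "mass": mass,
        "smr": smr,
        "peak": peak,
        "duration_drawn": dur,
        "duration": bump_return_time(peak, dur, smr, cfg.return_fraction,
                                     cfg.bump_beta),
        "magnitude": bump_area(peak, dur, cfg.bump_beta),
        "mo2_midpoints": truth_mo2,
        "regurgitated": regurgitated,
    }
    return trace, truth


def simulate_resp_group(cfg: SimConfig):
    """Simulate both genotype groups (cfg.n_per_group each).

    Returns (traces, truths) lists ordered wild-type first."""
    rng = np.random.default_rng(cfg.seed)
    traces, truths = [], []
    for genotype in ("wt", "ko"):
        for i in range(cfg.n_per_group):
            trace, truth = simulate_resp_trace(
                cfg, animal_id=f"{genotype}{i + 1:02d}", genotype=genotype,
                rng=rng)
            traces.append(trace)
            truths.append(truth)
    return traces, truths


# ---------------------------------------------------------------------------
# fluxes

def simulate_flux_series(cfg: SimConfig, animal_id: str = "A1",
                         genotype: str = "wt",
                         rng: np.random.Generator | None = None):
    """Simulate a static-chamber water-sample series.

    True fluxes are piecewise constant per sampling interval: baseline plus
    a post-feed excess decaying with the configured half-life, evaluated at
    the interval midpoint.  Concentrations accumulate through the chamber
    mass balance; truth stores the per-interval J values, so a noise-free
    round trip through `net_flux` is exact.

    Returns (samples DataFrame(time_h, tan_umol_l, talk_ueq_l), truth).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ko = genotype == "ko"
    times = np.asarray(cfg.flux_sample_times, dtype=float)
    v, m = cfg.flux_chamber_l, cfg.flux_mass_kg

    def series(baseline: float, excess: float, start_conc: float):
        conc = np.empty(len(times))
        conc[0] = start_conc
        js = []
        for k in range(len(times) - 1):
            t_mid = 0.5 * (times[k] + times[k + 1])
            j = baseline + excess * 0.5 ** (t_mid / cfg.flux_decay_half_life_h)
            js.append(j)
            dt = times[k + 1] - times[k]
            conc[k + 1] = conc[k] + j * m * dt / v
        return conc, np.asarray(js)

    tan, j_tamm = series(cfg.tamm_baseline,
                         cfg.tamm_postfeed_excess_ko if ko
                         else cfg.tamm_postfeed_excess_wt, 0.0)
    talk, j_talk = series(cfg.talk_baseline,
                          cfg.talk_postfeed_excess_ko if ko
                          else cfg.talk_postfeed_excess_wt,
                          cfg.talk_start_ueq_l)
    if cfg.flux_conc_noise_sd > 0:
        tan = tan + rng.normal(0.0, cfg.flux_conc_noise_sd, len(times))
        talk = talk + rng.normal(0.0, cfg.flux_conc_noise_sd, len(times))
    samples = pd.DataFrame({"time_h": times,
                            "tan_umol_l": np.maximum(tan, 0.0),
                            "talk_ueq_l": talk})
    truth = {
        "animal_id": animal_id,
        "genotype": genotype,
        "volume_l": v,
        "mass_kg": m,
        "j_tamm": j_tamm,
        "j_talk": j_talk,
        "baseline_tamm": cfg.tamm_baseline,
    }
    return samples, truth


# ---------------------------------------------------------------------------
# growth

def _trial_periods(cfg: SimConfig):
    ctrl, drug, rec = cfg.period_weeks
    labels = (["control"] * ctrl + ["omeprazole"] * drug + ["recovery"] * rec)
    return labels[:cfg.n_weeks]


def simulate_growth(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Simulate the weekly growth trial for both genotypes.

    Mass grows exponentially at the base specific growth rate; during the
    configured depressed weeks the rate is multiplied by
    (1 − drug_depression_fraction).  Feed intake is the daily ration
    (fraction of week-start mass) summed over 7 days.  Growth is
    genotype-independent, as observed in the source study.

    Returns (records DataFrame, truth dict of weekly true G per week)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    labels = _trial_periods(cfg)
    g_base = cfg.base_sgr_pct_per_day / 100.0
    weekly_g = {
        w: g_base * (1.0 - cfg.drug_depression_fraction
                     if w in cfg.depressed_weeks else 1.0)
        for w in range(1, cfg.n_weeks + 1)
    }
    rows = []
    for genotype in ("wt", "ko"):
        for i in range(cfg.n_per_group):
            animal = f"{genotype}{i + 1:02d}"
            mass = max(rng.normal(cfg.start_mass_g, cfg.start_mass_sd_g),
                       0.02)
            obs = mass * (np.exp(rng.normal(0.0, cfg.mass_noise_cv))
                          if cfg.mass_noise_cv > 0 else 1.0)
            rows.append({"animal_id": animal, "genotype": genotype,
                         "week": 0, "period": "start", "mass_g": obs,
                         "feed_mg": np.nan})
            for w in range(1, cfg.n_weeks + 1):
                feed_mg = mass * cfg.growth_ration_fraction * 7 * 1000.0
                mass = mass * np.exp(weekly_g[w] * 7.0)
                obs = mass * (np.exp(rng.normal(0.0, cfg.mass_noise_cv))
                              if cfg.mass_noise_cv > 0 else 1.0)
                rows.append({"animal_id": animal, "genotype": genotype,
                             "week": w, "period": labels[w - 1],
                             "mass_g": obs, "feed_mg": feed_mg})
    records = pd.DataFrame(rows)
    truth = {"weekly_g_pct_per_day": {w: 100.0 * g
                                      for w, g in weekly_g.items()},
             "base_sgr_pct_per_day": cfg.base_sgr_pct_per_day,
             "depressed_weeks": tuple(cfg.depressed_weeks)}
    return records, truth


# ---------------------------------------------------------------------------
# qPCR

def simulate_ct_table(cfg: SimConfig,
                      rng: np.random.Generator | None = None):
    """Simulate a Ct table with multi-reference normalisation structure.

    Reference genes are constant in expectation across groups; each target
    gene is shifted in the 'ko' group by −log2_effect cycles (so the true
    fold change is 2^effect).  A per-sample loading offset common to all
    genes tests normalisation invariance.

    Returns (CtTable DataFrame, truth dict of per-target expected folds)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rows = []
    for group in ("wt", "ko"):
        for i in range(cfg.n_per_group):
            sample = f"{group}{i + 1:02d}"
            offset = (rng.normal(0.0, cfg.qpcr_loading_sd)
                      if cfg.qpcr_loading_sd > 0 else 0.0)

            def noise():
                return (rng.normal(0.0, cfg.ct_noise_sd)
                        if cfg.ct_noise_sd > 0 else 0.0)

            for gene, base in zip(cfg.reference_genes,
                                  cfg.reference_base_ct):
                rows.append({"sample_id": sample, "group": group,
                             "gene": gene, "ct": base + offset + noise(),
                             "efficiency": 100.0, "is_reference": True})
            for gene, base in cfg.target_base_ct.items():
                shift = (-cfg.target_log2_effect.get(gene, 0.0)
                         if group == "ko" else 0.0)
                rows.append({"sample_id": sample, "group": group,
                             "gene": gene,
                             "ct": base + shift + offset + noise(),
                             "efficiency": cfg.qpcr_efficiency.get(gene,
                                                                   100.0),
                             "is_reference": False})
    table = pd.DataFrame(rows)
    truth = {gene: 2.0 ** eff
             for gene, eff in cfg.target_log2_effect.items()}
    return table, truth
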