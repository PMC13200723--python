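# Methods

This note records the models implemented in `sdaflux`, the defaults and the
reasoning behind the genuinely open design choices, and what the synthetic
generators do and do not emulate.

## Respirometry

**Per-cycle ṀO₂.** In intermittent-flow respirometry the chamber is sealed
("measure" phase) and the O₂ concentration declines; flushing renews the
water between cycles. Within each measure cycle the O₂ decline is modelled
as linear and fitted by ordinary least squares; the mass-specific rate is
ṀO₂ = −b·V_eff/M with b the slope (µmol l⁻¹ h⁻¹), V_eff the chamber volume
minus the fish volume (fish density assumed 1 g ml⁻¹) in litres, and M the
wet mass in g. Cycles fail QC when they have fewer than 5 samples, when r²
of the fit is below 0.9, or when the slope is positive (O₂ cannot rise in a
sealed chamber; rising traces indicate bubbles or probe faults). A
perfectly flat cycle has undefined r²; it is accepted as a clean zero-slope
fit only when the residual s.d. is below 1e-9 µmol l⁻¹, otherwise it is a
noisy cycle and fails on r². Background (microbial) respiration correction
is not applied by default; a blank-trace slope can be subtracted from the
raw slopes upstream if available.

**SMR.** The standard metabolic rate is estimated from qc-passing cycles in
the final 25% of the record, by which time the post-prandial response has
subsided. The default estimator is the plain mean of those cycles. A
low-quantile estimator (mean of the lowest 20% of window cycles) is also
provided because it is common practice when records are contaminated by
undetected activity; however, it carries a deterministic order-statistic
bias of about −1.4 cycle-noise s.d. (mean of the lower 20% tail of a
Gaussian), which at a cycle noise of 0.25 µmol O₂ g⁻¹ h⁻¹ on an SMR near
5.3 is a −6 to −7% bias — large enough to matter for parameter recovery.
Since activity here is handled explicitly by the QC flags, the unbiased
mean is the better default; the quantile method remains selectable
(`SDAConfig.smr_method`).

**SDA extraction.** The response starts at the first qc-passing cycle: the
animals are fed immediately before entering the chamber, so the record
begins inside the response. The endpoint is the midpoint time of the first
cycle, at or after the observed peak, that begins a run of 3 consecutive
cycles at or below SMR × 1.10; the 10% tolerance is the conventional
"returned to SMR" criterion and guards against noise around the asymptote,
and the run requirement guards against single low cycles. The search starts
at the peak because the earliest cycles — before the response has risen —
can themselves sit at the threshold. If no run is found the endpoint clips
to the record end. Net peak is max(ṀO₂) − SMR over [start, end]; magnitude
is the trapezoidal integral of (ṀO₂ − SMR)⁺ over the same span, in
µmol O₂ g⁻¹ (an amount of oxygen per gram, since it is a time-integral of
a rate). Part of the source literature prints SDA magnitude with the rate
unit (µmol O₂ g⁻¹ h⁻¹); `SDAResult.magnitude_printed_units` repeats the
number under that convention without rescaling so tables can be compared
directly.

An optional centred rolling-median smoother (`smooth_cycles`) can be
applied before peak/endpoint detection. It is off by default: a width-3
median flattens genuine extrema (a clean triangular peak of height 3 would
be reported as 2.8) and breaks exact noise-free round trips; it is useful
only for visibly spiky records.

**Exclusions.** An animal is flagged "activity" when more than 40% of its
cycles fail QC (persistent motion makes the O₂ declines non-linear), and
"regurgitation" when the extracted duration is below 4 h — a response that
short indicates the meal was vomited, since digestion of a full meal takes
substantially longer. Flagged animals still carry their computed numbers;
downstream summaries drop them.

## Fluxes

Net fluxes follow J_X = ([X]_f − [X]_i)·V/(M·t) with excretion into the
water positive. The net acid–base flux is J_TAlk − J_TAmm; negative values
indicate net base uptake (acid excretion), positive values net base
excretion. Titratable alkalinity of a water sample is titrant equivalents
per sample litre (×10⁶ to µEq l⁻¹); the two-stage protocol (automatic
titration to pH 4.3, manual finish to pH 4.0) is collapsed into the total
titrant volume, which is what the acid–base arithmetic needs.

Cumulative above-baseline ammonia is Σ max(J_TAmm − baseline, 0)·M·t over
contiguous intervals — exact for piecewise-constant fluxes. The baseline is
user-supplied (typically the pre-feed or unfed-control mean); no single
operational definition is imposed. The fraction of meal ammonia excreted is
100 × excreted/meal TAN and may legitimately exceed 100% when amino-acid
catabolism adds ammonia beyond direct absorption; that case is flagged, not
clipped.

Speciation uses the apparent-pK model: NH₃ = TAN/(1 + 10^(pK′−pH)),
P_NH₃ = NH₃/α_NH₃. pK′ and α_NH₃ depend on temperature and ionic strength
and must be supplied; `DEFAULT_SPECIATION_23C` (pK′ 9.33, α_NH₃ 8.1e4
µmol l⁻¹ torr⁻¹, from the thermodynamic NH₄⁺ pK with a modest
ionic-strength correction and the Henry-law solubility of NH₃ near 23 °C)
is a documented generic starting point, not a hard-coded assumption.

**Acid-cost model.** The direct cost of gastric acid secretion is the acid
load neutralised per gram of body mass divided by ρ, the H⁺ secreted per O₂
consumed (published estimates range from 5.0 down to 2.3 once proton
back-leak is accounted for). The load can be derived as buffer capacity
(µmol H⁺ (g meal)⁻¹ pH⁻¹) × ΔpH × ration (g meal per g body) — a
dimensionally closed product needing no extra scale factor — or supplied
directly when the meal's buffer curve is not available. The share of SDA is
100 × O₂ cost / SDA magnitude. The model deliberately excludes indirect
costs (mucus and HCO₃⁻ secretion, chyme neutralisation), so its share is a
lower bound on the total contribution of acid secretion.

## Growth

G = 100·(ln M₂ − ln M₁)/Δt in % day⁻¹ (the e-based instantaneous rate g is
returned alongside); weekly Δt defaults to 7 days. Weekly rates telescope
exactly to the whole-trial rate in log space. FCR = feed/gain; a
non-positive gain yields a flagged NaN rather than an exception, since an
interval without growth is a data feature, not an error. Fulton's
K = 100·M/L³.

## qPCR

The 2^−ΔΔCt estimator: per sample, the reference level is the arithmetic
mean of the reference-gene Cts — identical to geometric-mean normalisation
of the linear quantities, which is the standard multi-reference scheme. An
alternative (`ref_average="linear_mean"`) averages the linear quantities
arithmetically instead. ΔΔCt is referenced to the calibrator group's mean
ΔCt, so the calibrator's geometric-mean fold is exactly 1. Technical
replicates are averaged on the Ct scale before ΔCt. Amplification
efficiencies are stored and reported; quantification uses the pure base-2
model by default, with a Pfaffl-style efficiency-corrected mode
(per-gene base 1 + E/100) behind a flag — the two coincide at E = 100%.

## Synthetic generators

The generators define the study conditions used throughout the tests.

**Respirometry.** ṀO₂(t) = SMR + peak · p(t/D), where p is a gamma-density
(shape 2) profile with its tail value subtracted so that its support is
exactly [0, D] and its maximum is 1 (decay rate β = 4, mode at D/4). Group
means: SMR 5.3 (wild type) vs 5.1 (knockout) µmol O₂ g⁻¹ h⁻¹, wild-type
peak 3.03 and bump timescale 15.25 h; knockout durations are scaled by
−11% and peaks by the ratio that makes the magnitude contrast −21.8%.
Between-animal s.d. (SMR 1.1, peak 0.5, duration 1.5) are set from the
source study's reported group spreads (s.e.m.·√n). Per-cycle Gaussian noise
(default 0.25 µmol O₂ g⁻¹ h⁻¹) is added at the cycle midpoints, and O₂
samples are back-computed through the chamber mass balance, so the ṀO₂
regression inverts the generator exactly in the noise-free limit. Records
are 24 h of 15-min cycles (10 min measure, 1-min samples). Activity spikes
(a Poisson process) inject within-cycle O₂ noise that drives r² below the
QC gate; regurgitation truncates the bump to 3 h.

Truth records store the drawn SMR/peak/timescale, the *operational*
duration — the analytic time at which the bump falls to 10% of SMR, the
same return criterion the analyzer uses — and the analytic bump area.
Recovery is therefore judged against the quantity the SDA definition
actually measures; the drawn timescale D is retained separately.

**Fluxes.** True fluxes are piecewise constant per sampling interval
(0/3/6/9/24 h grid): baseline plus a post-feed excess decaying with a 6-h
half-life, the ammonia excess 3.65-fold smaller in the knockout group.
Concentrations accumulate through the chamber mass balance, so `net_flux`
recovers the true J values exactly without measurement noise.

**Growth.** Exponential mass growth at 2.36% day⁻¹ over a 3-control /
2-omeprazole / 3-recovery week structure; the rate is multiplied by
(1 − 0.452) in the second omeprazole week and the first two recovery weeks,
matching the observed depression window. Feed is a 3% body-mass daily
ration summed per week.

**qPCR.** Reference genes constant in expectation; targets shifted by
per-gene log₂ effects in the knockout group (default cck at −1, i.e. a
halving); a per-sample loading offset common to all genes exercises the
normalisation.

What the generators do **not** emulate: optode drift and temperature
sensitivity, background (microbial) respiration, diel activity rhythms,
chamber mixing lags, nitrification in flux chambers, correlated biological
traits (e.g. SMR–peak covariance), inter-plate qPCR effects, or
non-Gaussian individual variation. Passing recovery tests therefore show
the estimators are consistent under the stated noise model, not that real
traces are this clean.

## Statistics

Two-group comparisons follow the gate: Shapiro–Wilk on each group
(α = 0.05); if both pass, a median-centred Levene test chooses Student
(equal variances) or Welch; any normality failure routes to the Wilcoxon
rank-sum test. Zero-variance samples are treated as non-normal
(Shapiro–Wilk is undefined there). Policy objects force specific branches;
the respirometry endpoints (SMR, duration, net peak, magnitude) use the
forced-Welch policy, the branch appropriate to their unequal group
variances. The genotype × week analysis is a mixed (between × within)
repeated-measures ANOVA (delegated to pingouin) with statsmodels Tukey HSD
week contrasts; all-zero-variance inputs are reported as F = 0, p = 1
rather than NaN. Levene-on-medians was chosen as the homoscedasticity check
for its robustness to non-normality.

## Problem sizes and determinism

Validation uses 12 animals per genotype per study (96 cycles each), 100
replicate studies for the detection-rate estimate, 50 samples per group for
the noisy qPCR recovery, and 1000 random inputs per elementary-operation
oracle check. All randomness flows through `numpy.random.default_rng`
seeded from a single integer; identical seeds give bit-identical outputs.

## Known limitations

* With between-animal dispersion set to the source study's own reported
  spreads, a Welch test on SDA magnitude at n = 12 + 12 has roughly 80–85%
  power (the acceptance script's `welch_detection_rate_pct` measures this
  directly); single replicates can and do fail to reach p < 0.05. This is
  a property of the study conditions, not of the estimator.
* SDA duration is grid-limited (one cycle, 0.25 h) and its endpoint
  detection is mildly biased late under noise (the below-threshold run must
  assemble); group means stay within a few percent of truth.
* Magnitude integrates only to the detected endpoint, so the shallow tail
  of the response below the return threshold is partly excluded (≈2–3% of
  the area for the default bump shape).
* The flux generator's piecewise-constant truth makes interval fluxes
  identifiable exactly; real chamber concentrations evolve continuously and
  interval fluxes are then time-averages.
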