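# sdaflux

Post-prandial energetics and nitrogen/acid–base budget analysis for
small-fish digestive physiology experiments — the kind of study that asks
what gastric acid secretion costs an animal by comparing wild-type fish
with proton-pump (H⁺/K⁺-ATPase, *atp4a*) knockouts around a meal.

`sdaflux` turns four plain tabular data streams into the standard endpoints
of such a study:

* **Respirometry** — intermittent-flow O₂ traces → per-cycle ṀO₂ from the
  O₂-decline slope (ṀO₂ = −b·V_eff/M, µmol O₂ g⁻¹ h⁻¹), standard metabolic
  rate (SMR) from the late post-absorptive window, and the specific dynamic
  action (SDA): net peak (max ṀO₂ − SMR), duration (time to return to
  within a tolerance of SMR) and magnitude (∫(ṀO₂ − SMR)⁺ dt, µmol O₂ g⁻¹),
  with activity/regurgitation exclusion rules.
* **Static-chamber fluxes** — water samples → net mass-specific fluxes
  J_X = ([X]_f − [X]_i)·V/(M·t) for total ammonia (TAN) and titratable
  alkalinity, the net acid–base flux J_TAlk − J_TAmm, cumulative
  above-baseline TAN, the fraction of meal ammonia excreted, NH₃/NH₄⁺
  speciation (pK′ model), and a stoichiometric model of the direct O₂ cost
  of acid secretion (acid load / ρ with ρ the H⁺:O₂ ratio).
* **Growth trials** — weekly masses and feed → specific growth rate
  G = 100·(ln M₂ − ln M₁)/Δt (% day⁻¹), feed conversion ratio, Fulton's K.
* **qPCR** — Ct tables → 2^−ΔΔCt fold changes with multi-reference
  (geometric-mean) normalisation and an optional efficiency-corrected mode.

A seeded synthetic-data generator (`sdaflux.synth`) emulates every input
stream with recorded ground truth, so the whole pipeline is validated by
parameter-recovery and round-trip tests; `sdaflux.stats` reproduces the
group-comparison logic (Shapiro–Wilk → Levene → Student/Welch t, Wilcoxon
fallback; genotype × week repeated-measures ANOVA with Tukey contrasts).

## Worked example

```python
import sdaflux as sf

# simulate a 12+12 animal respirometry study and run the full pipeline
study = sf.respirometry_study(sf.SimConfig(seed=42, n_per_group=12))
print(study.groupby("genotype")[["smr", "duration", "net_peak",
                                 "magnitude"]].mean().round(2))
#            smr  duration  net_peak  magnitude
# genotype
# ko        5.38     10.77      2.70      16.22
# wt        5.27     12.23      3.41      23.57
print(round(sf.percent_reduction(23.57, 16.22), 1))  # 31.2 (% reduction)
print(round(sf.magnitude_welch_p(study), 4))         # 0.0001

# direct O2 cost of gastric acid secretion against an SDA magnitude of
# 21.47 µmol O2/g: acid load 2.82 µmol H+/g at 5 H+ per O2
model = sf.acid_cost(sf.AcidCostModel(h_o2_ratio=5.0, acid_load=2.82),
                     sda_magnitude=21.47)
print(round(model.o2_cost, 3), round(model.sda_share, 1))  # 0.564 2.6
```

The group means are the pipeline's estimates for that seed's cohort; the
SMRs are statistically indistinguishable while the knockout group's SDA
magnitude is sharply lower (Welch p ≈ 1e-4). The acid-cost numbers say
that pumping 2.82 µmol H⁺ per gram of body mass costs 0.564 µmol O₂ g⁻¹ —
only ~2.6% of the whole SDA response.

A CLI mirrors the library for file-based use:

```sh
sdaflux simulate --what resp --seed 1 --out sim/
sdaflux respirometry --trace sim/trace.csv --meta sim/meta.csv --out-dir out/
sdaflux fluxes --samples samples.csv --meta chambers.csv --out fluxes.csv
sdaflux growth --table growth.csv --out growth_metrics.csv
sdaflux qpcr --table ct.csv --target cck --calibrator wt --out folds.csv
```

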