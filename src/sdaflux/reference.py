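"""Published summary statistics of the gastric proton-pump knockout study.

These are the printed group means (± s.e.m. where noted in comments) used
as inputs for derived quantities (percent contrasts, the acid-cost model's
worked numbers) and as anchors for the synthetic study conditions.  Group
order is (wild-type atp4a+/+, knockout atp4a−/−) throughout.
"""

from __future__ import annotations

# respirometry endpoints (µmol O2 g⁻¹ h⁻¹ except duration in h)
SMR = (5.42, 5.10)
SDA_DURATION_H = (15.25, 13.58)
SDA_NET_PEAK = (3.03, 2.80)
SDA_MAGNITUDE = (21.47, 16.78)

# nitrogen budget
CHYME_TAN_MMOL_L = (1.65, 2.55)   # gastric chyme total ammonia
MEAL_TAN_UMOL = 0.077             # bloodworm meal ammonia content
JTAMM_FOLD_WT_OVER_KO = 3.65      # post-feed ammonia excretion contrast

# acid-secretion cost model
H_O2_RATIOS = (5.0, 2.3)          # published H+ secreted per O2 consumed
ACID_O2_COST = (0.564, 1.226)     # µmol O2 g⁻¹ body at the two ratios

# growth trial
INITIAL_MASS_G = (0.0865, 0.1155)  # trial start (Results labelling)
FINAL_MASS_G = (0.3234, 0.2469)
TRIAL_DAYS = 56                    # 8 weekly intervals
OMEPRAZOLE_SGR_DEPRESSION = 0.452
RATION_FRACTION = 0.03             # daily growth-trial ration, fraction Mb
MEAL_FRACTION = 0.05               # respirometry/flux bloodworm meal
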