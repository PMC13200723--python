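"""Group-comparison logic as a thin, auditable layer over standard tests.

`compare_groups` reproduces the decision tree used for two-group endpoint
comparisons: Shapiro–Wilk normality on each group (alpha 0.05), then a
Levene (median-centred) homoscedasticity check choosing between Student and
Welch t-tests, falling back to the Wilcoxon rank-sum test when normality
fails.  Every decision is recorded in the result's trail.  `rm_anova` runs
the genotype × week repeated-measures (mixed) ANOVA with Tukey HSD week
contrasts, delegating to pingouin and statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare_groups", "rm_anova",
           "percent_reduction"]

ALPHA = 0.05


def percent_reduction(reference: float, value: float) -> float:
    """100 × (reference − value) / reference."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (reference - value) / reference


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    df: float
    p_value: float
    decision_trail: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if not self.decision_trail:
            raise ValueError("decision trail must not be empty")


def _normal(x: np.ndarray, trail: list[str], label: str) -> bool:
    if np.ptp(x) == 0.0:
        trail.append(f"shapiro {label}: degenerate (zero variance)")
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sps.shapiro(x).pvalue
    ok = p >= ALPHA
    trail.append(f"shapiro {label}: p={p:.4g} -> "
                 f"{'normal' if ok else 'non-normal'}")
    return ok


def compare_groups(a, b, policy: str = "auto") -> ComparisonResult:
    """Compare two independent samples with a recorded decision trail.

    policy "auto" follows the full gate (Shapiro → Levene → Student/Welch,
    else Wilcoxon rank-sum); "welch" forces the Welch t-test, the branch
    used for the respirometry endpoints where variances were unequal;
    "student" and "wilcoxon" force those tests.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs n >= 3")
    trail: list[str] = []

    if policy == "auto":
        normal = _normal(a, trail, "a") & _normal(b, trail, "b")
        if not normal:
            branch = "wilcoxon"
        else:
            lev = sps.levene(a, b, center="median").pvalue
            equal = lev >= ALPHA
            trail.append(f"levene(median): p={lev:.4g} -> "
                         f"{'equal' if equal else 'unequal'} variance")
            branch = "student" if equal else "welch"
    elif policy in ("welch", "student", "wilcoxon"):
        branch = policy
        trail.append(f"policy: forced {policy}")
    else:
        raise ValueError(f"unknown policy {policy!r}")

    if branch == "wilcoxon":
        res = sps.ranksums(a, b)
        trail.append("test: wilcoxon rank-sum")
        return ComparisonResult("wilcoxon rank-sum", float(res.statistic),
                                float("nan"), float(res.pvalue), trail)
    equal_var = branch == "student"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    name = "student t" if equal_var else "welch t"
    trail.append(f"test: {name}")
    return ComparisonResult(name, float(res.statistic), float(res.df),
                            float(res.pvalue), trail)


def rm_anova(table: pd.DataFrame, dv: str = "value", within: str = "week",
             between: str = "genotype", subject: str = "subject"):
    """Two-way repeated-measures (mixed) ANOVA plus Tukey HSD week
    contrasts.

    ``table`` is long-format with one row per subject × week.  Each subject
    must be observed in every week; missing cells raise with a listing.
    Returns (effects DataFrame with Source/F/df1/df2/p, tukey DataFrame).
    Zero-variance effects are reported as F = 0, p = 1.
    """
    import pingouin as pg
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    weeks = sorted(table[within].unique())
    missing = []
    for subj, grp in table.groupby(subject):
        absent = set(weeks) - set(grp[within])
        if absent:
            missing.append(f"{subj}: weeks {sorted(absent)}")
    if missing:
        raise ValueError("missing cells: " + "; ".join(missing))

    if np.ptp(table[dv].to_numpy(float)) == 0.0:
        effects = pd.DataFrame({
            "Source": [between, within, "Interaction"],
            "F": 0.0, "df1": np.nan, "df2": np.nan, "p": 1.0})
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(data=table, dv=dv, within=within,
                                 subject=subject, between=between)
        effects = aov.rename(columns={"DF1": "df1", "DF2": "df2",
                                      "p-unc": "p", "p_unc": "p"})
        effects = effects[["Source", "F", "df1", "df2", "p"]].copy()
        zero = ~np.isfinite(effects["F"])
        effects.loc[zero, "F"] = 0.0
        effects.loc[zero, "p"] = 1.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate all-equal contrasts
        tk = pairwise_tukeyhsd(table[dv].to_numpy(float),
                               table[within].astype(str).to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=[str(c) for c in tk.summary().data[0]])
    return effects, tukey
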