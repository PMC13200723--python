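"""Relative qPCR quantification by the 2^-ddCt method with multi-reference
normalisation.

Per sample, the reference level is the arithmetic mean of the reference-gene
Cts (equivalent to geometric-mean normalisation of the linear quantities).
dCt = Ct_target − Ct_ref; ddCt = dCt − mean dCt of the calibrator group;
fold = 2^−ddCt.  Technical replicate Cts are averaged before dCt.

An efficiency-corrected mode replaces the base 2 with per-gene
amplification factors (1 + E/100) in the Pfaffl style; with E = 100% it
reduces exactly to 2^-ddCt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["validate_ct_table", "ddct"]

CT_COLUMNS = ("sample_id", "group", "gene", "ct", "is_reference")


def validate_ct_table(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if "efficiency" in table.columns:
        eff = table["efficiency"].dropna()
        if ((eff <= 50) | (eff >= 150)).any():
            raise ValueError("efficiencies must lie in (50, 150) percent")
    if not table["is_reference"].any():
        raise ValueError("need at least one reference gene")


def _reference_ct(ref: pd.DataFrame, mode: str) -> float:
    cts = ref["ct"].to_numpy(float)
    if mode == "ct_mean":
        # arithmetic mean of Cts == geometric mean of linear quantities
        return float(np.mean(cts))
    if mode == "linear_mean":
        return float(-np.log2(np.mean(2.0 ** -cts)))
    raise ValueError(f"unknown ref_average mode {mode!r}")


def ddct(table: pd.DataFrame, target: str, calibrator_group: str,
         ref_average: str = "ct_mean",
         efficiency_corrected: bool = False) -> pd.DataFrame:
    """Per-sample fold change of ``target`` relative to the calibrator group.

    Returns a DataFrame (sample_id, group, delta_ct, delta_delta_ct, fold).
    Raises when the target is absent, the calibrator group is empty, or a
    sample lacks any of the table's reference genes.
    """
    validate_ct_table(table)
    # average technical replicates
    agg = {"ct": "mean", "is_reference": "first", "group": "first"}
    if "efficiency" in table.columns:
        agg["efficiency"] = "first"
    tab = (table.groupby(["sample_id", "gene"], as_index=False, sort=False)
           .agg(agg))

    ref_genes = sorted(tab.loc[tab["is_reference"], "gene"].unique())
    if target not in set(tab["gene"]):
        raise ValueError(f"target gene {target!r} not in table")

    rows = []
    for sample, grp in tab.groupby("sample_id", sort=False):
        refs = grp[grp["gene"].isin(ref_genes) & grp["is_reference"]]
        have = set(refs["gene"])
        if have != set(ref_genes):
            missing = sorted(set(ref_genes) - have)
            raise ValueError(
                f"sample {sample!r} missing reference genes: {missing}")
        tgt = grp[grp["gene"] == target]
        if tgt.empty:
            continue
        rows.append({
            "sample_id": sample,
            "group": grp["group"].iloc[0],
            "target_ct": float(tgt["ct"].iloc[0]),
            "ref_ct": _reference_ct(refs, ref_average),
            "ref_cts": refs.set_index("gene")["ct"].to_dict(),
        })
    res = pd.DataFrame(rows)
    if res.empty or not (res["group"] == calibrator_group).any():
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")

    if not efficiency_corrected:
        res["delta_ct"] = res["target_ct"] - res["ref_ct"]
        cal = res.loc[res["group"] == calibrator_group, "delta_ct"].mean()
        res["delta_delta_ct"] = res["delta_ct"] - cal
        res["fold"] = 2.0 ** -res["delta_delta_ct"]
    else:
        eff = tab.groupby("gene")["efficiency"].first()
        if eff.isna().any():
            raise ValueError("efficiency-corrected mode needs an "
                             "'efficiency' column for every gene")
        amp = 1.0 + eff / 100.0
        cal_mask = res["group"] == calibrator_group
        # Pfaffl-style: per-gene amplification factor raised to the -dCt
        # relative to the calibrator-group mean Ct of that gene
        tgt_cal = res.loc[cal_mask, "target_ct"].mean()
        num = amp[target] ** -(res["target_ct"] - tgt_cal)
        denom = np.ones(len(res))
        for gene in ref_genes:
            cts = res["ref_cts"].map(lambda d: d[gene]).astype(float)
            gene_cal = cts[cal_mask].mean()
            denom = denom * amp[gene] ** -(cts - gene_cal)
        denom = denom ** (1.0 / len(ref_genes))
        res["fold"] = (num / denom).to_numpy(float)
        res["delta_ct"] = res["target_ct"] - res["ref_ct"]
        res["delta_delta_ct"] = -np.log2(res["fold"])
    return res[["sample_id", "group", "delta_ct", "delta_delta_ct", "fold"]]
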