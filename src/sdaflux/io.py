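"""CSV readers/writers for the plain tabular dialects the pipeline uses.

Respirometry traces are long-format (animal_id, time_h, o2_umol_l, phase,
cycle) with a companion metadata table (animal_id, genotype, mass_g,
chamber_ml).  Water samples, growth records and Ct tables are single tidy
CSVs.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .respirometry import RespTrace, SDAResult

__all__ = ["read_resp_traces", "traces_to_frames", "write_resp_traces",
           "sda_results_to_frame", "read_ct_table", "read_growth_records"]


def read_resp_traces(trace_csv, meta_csv) -> list[RespTrace]:
    """Load one RespTrace per animal from a long trace CSV + metadata CSV."""
    traces = pd.read_csv(trace_csv)
    meta = pd.read_csv(meta_csv).set_index("animal_id")
    out = []
    for animal, grp in traces.groupby("animal_id", sort=False):
        if animal not in meta.index:
            raise ValueError(f"no metadata for animal {animal!r}")
        m = meta.loc[animal]
        samples = pd.DataFrame({
            "time": grp["time_h"].to_numpy(float),
            "o2": grp["o2_umol_l"].to_numpy(float),
            "phase": grp["phase"].to_numpy(),
            "cycle": grp["cycle"].to_numpy(),
        })
        out.append(RespTrace(
            animal_id=str(animal), genotype=str(m.get("genotype", "")),
            mass=float(m["mass_g"]), chamber_volume=float(m["chamber_ml"]),
            fish_volume=(float(m["fish_ml"]) if "fish_ml" in m.index
                         and pd.notna(m["fish_ml"]) else None),
            samples=samples))
    return out


def traces_to_frames(traces: list[RespTrace]):
    """Inverse of :func:`read_resp_traces`: (trace frame, metadata frame)."""
    parts, meta = [], []
    for tr in traces:
        part = tr.samples.rename(columns={"time": "time_h",
                                          "o2": "o2_umol_l"}).copy()
        part.insert(0, "animal_id", tr.animal_id)
        parts.append(part)
        meta.append({"animal_id": tr.animal_id, "genotype": tr.genotype,
                     "mass_g": tr.mass, "chamber_ml": tr.chamber_volume,
                     "fish_ml": tr.fish_volume})
    return pd.concat(parts, ignore_index=True), pd.DataFrame(meta)


def write_resp_traces(traces: list[RespTrace], out_dir) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame, meta = traces_to_frames(traces)
    trace_path = out_dir / "trace.csv"
    meta_path = out_dir / "meta.csv"
    frame.to_csv(trace_path, index=False)
    meta.to_csv(meta_path, index=False)
    return trace_path, meta_path


def sda_results_to_frame(results: list[SDAResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def read_ct_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path)
    if "efficiency_pct" in tab.columns:
        tab = tab.rename(columns={"efficiency_pct": "efficiency"})
    tab["is_reference"] = tab["is_reference"].astype(bool)
    return tab


def read_growth_records(path) -> pd.DataFrame:
    return pd.read_csv(path)
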