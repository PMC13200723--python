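import numpy as np
import pandas as pd
import pytest

from sdaflux.respirometry import MO2Series, RespTrace


def make_series(values, times=None, qc_pass=None, animal_id="A1"):
    """MO2Series straight from per-cycle values (all passing by default)."""
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    if qc_pass is None:
        qc_pass = np.ones(len(values), dtype=bool)
    cycles = pd.DataFrame({
        "cycle": np.arange(len(values)),
        "midpoint_time": np.asarray(times, dtype=float),
        "mo2": values,
        "r_squared": 1.0,
        "n_points": 10,
        "qc_pass": qc_pass,
        "qc_reason": np.where(qc_pass, "", "low r2"),
    })
    return MO2Series(animal_id=animal_id, cycles=cycles)


def make_trace(cycle_o2, dt_h=1.0 / 60.0, mass=0.4, chamber_ml=40.0,
               animal_id="A1"):
    """RespTrace from a list of per-cycle O2 sample arrays (measure only)."""
    frames, t0 = [], 0.0
    for c, o2 in enumerate(cycle_o2):
        o2 = np.asarray(o2, dtype=float)
        frames.append(pd.DataFrame({
            "time": t0 + np.arange(len(o2)) * dt_h,
            "o2": o2,
            "phase": "measure",
            "cycle": c,
        }))
        t0 += len(o2) * dt_h + 5.0 / 60.0  # flush gap
    return RespTrace(animal_id=animal_id, mass=mass,
                     chamber_volume=chamber_ml,
                     samples=pd.concat(frames, ignore_index=True))


@pytest.fixture
def tent_series():
    """Triangular SDA bump: SMR 5, peak +3 at 7.5 h, back to SMR at 15 h,
    sampled every 0.5 h."""
    t = np.arange(0.0, 15.0 + 1e-9, 0.5)
    tent = np.where(t <= 7.5, t / 7.5, (15.0 - t) / 7.5)
    return make_series(5.0 + 3.0 * tent, times=t), 5.0
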