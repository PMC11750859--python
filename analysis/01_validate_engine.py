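#!/usr/bin/env python
"""Validate the cable solver against analytic passive oracles.

Checks, and tabulates in results/01_engine_validation.csv:
  * isopotential RC step response vs V0 + IR(1 - e^(-t/tau_m)), tau_m = 10 ms
  * sealed-end cable steady-state attenuation vs cosh((L-x)/lam)/cosh(L/lam)
  * somatic AP peak-time shift between dt = 0.1 ms and the 0.001 ms reference
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from mossyfiber.analysis import detect_spikes
from mossyfiber.fixtures import make_passive_references
from mossyfiber.morphology import build_mossy_fiber
from mossyfiber.protocols import Protocol
from mossyfiber.solver import CableSolver, run, steady_state

RESULTS = Path(__file__).resolve().parents[1] / "results"


def rc_check():
    cfg = {"geometry": {"soma": {"diameter_um": 10.0, "length_um": 10.0},
                        "axon": {"count": 1, "length_um": 10.0,
                                 "diameter_um": 10.0},
                        "bouton": {"count": 0}, "segments_per_um": 0.1}}
    m = build_mossy_fiber(cfg)
    ref = make_passive_references()
    solver = CableSolver(m, ())
    state = solver.init_state()
    dt, i_na = 0.01, 0.01
    i_vec = np.zeros(m.n_segments)
    i_vec[0] = i_na * 1e-3
    n = int(50.0 / dt)
    v = [state.v_mv[0]]
    for _ in range(n):
        solver.step(state, dt, i_vec)
        v.append(state.v_mv[0])
    t = np.arange(n + 1) * dt
    v_ref = ref.rc_step_response(t, -80.0, i_na, m.total_area_cm2)
    err = np.max(np.abs(np.asarray(v) - v_ref)) / (v_ref[-1] - v_ref[0])
    return dict(check="rc_step", metric="max_error_fraction_of_amplitude",
                value=err, tolerance=0.01)


def cable_check():
    cfg = {"geometry": {"soma": {"diameter_um": 0.2, "length_um": 1.0},
                        "axon": {"count": 1, "length_um": 400.0,
                                 "diameter_um": 0.2},
                        "bouton": {"count": 0}}}
    m = build_mossy_fiber(cfg)
    v = steady_state(m, (), clamp={0: -70.0}, tolerance_mv_per_ms=1e-6,
                     dt_ms=1.0)
    ref = make_passive_references(diameter_um=0.2)
    x = np.arange(m.n_segments) * 1.0
    att_sim = (v + 80.0) / 10.0
    att_ref = ref.cable_attenuation(x, (m.n_segments - 0.5) * 1.0)
    err = np.max(np.abs(att_sim - att_ref) / att_ref)
    return dict(check="cable_attenuation", metric="max_relative_error",
                value=err, tolerance=0.005)


def convergence_check():
    m = build_mossy_fiber()
    base = Protocol(n_pulses=1, t_pre_ms=30.0, t_post_ms=20.0,
                    recording_sites=("soma",))
    peaks = {}
    for dt in (0.1, 0.001):
        ts = run(m, base.with_(dt_ms=dt))
        peaks[dt] = detect_spikes(ts.time_ms, ts["soma"])[0].t_peak_ms
    return dict(check="ap_peak_time_convergence", metric="shift_ms",
                value=abs(peaks[0.1] - peaks[0.001]), tolerance=0.2)


def main():
    rows = [rc_check(), cable_check(), convergence_check()]
    df = pd.DataFrame(rows)
    df["passed"] = df["value"] < df["tolerance"]
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "01_engine_validation.csv"
    df.to_csv(out, index=False)
    print(df.to_string(index=False))
    print(f"\nwrote {out}")
    return 0 if df["passed"].all() else 1


if __name__ == "__main__":
    sys.exit(main())
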