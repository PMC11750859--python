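"""End-to-end reproducible runs: simulate a preset, analyze, write outputs.

``run_panel`` executes one named protocol preset, writes the traces (CSV and
HDF5), a JSON analysis summary (per-site spike tables, afterdischarge
statistics, latency orderings during vs after the train) and a run manifest
with SHA-256 checksums of every output, so a rerun can be verified
bit-identical.  ``sweep`` evaluates a grid of protocol modifications and
tabulates afterdischarge presence/frequency per grid point; it is resumable
and row-deterministic.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import time as _time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    afterdischarge_summary,
    annotate_half_durations,
    detect_spikes,
    latency_order,
)
from .channels import load_profile
from .morphology import build_mossy_fiber
from .protocols import ZONES, Protocol, preset
from .solver import run
from .traces import TraceSet

__all__ = ["run_panel", "analyze_traceset", "sweep"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def analyze_traceset(ts: TraceSet, stimulus_end_ms: float | None = None,
                     window_ms: float | None = None) -> dict:
    """Spike tables, afterdischarge summary and orderings for one trace set.

    The afterdischarge is assessed on the most distal recorded site (last in
    the site order), which is where the published traces are displayed; the
    per-site summaries are all included.
    """
    if stimulus_end_ms is None:
        stimulus_end_ms = ts.stimulus_end_ms
    out: dict = {"sites": {}, "stimulus_end_ms": stimulus_end_ms}
    if window_ms is None:
        total = float(ts.time_ms[-1])
        window_ms = (total - stimulus_end_ms) if stimulus_end_ms is not None else 0.0

    for site in ts.sites:
        evs = detect_spikes(ts.time_ms, ts[site])
        annotate_half_durations(ts.time_ms, ts[site], evs)
        table = [{
            "t_peak_ms": ev.t_peak_ms,
            "v_peak_mv": ev.v_peak_mv,
            "v_baseline_mv": ev.v_baseline_mv,
            "half_duration_ms": ev.half_duration_ms,
        } for ev in evs]
        entry: dict = {"n_spikes": len(evs), "spikes": table}
        if stimulus_end_ms is not None:
            train = [ev for ev in evs if ev.t_peak_ms <= stimulus_end_ms]
            if train:
                entry["first_train_half_duration_ms"] = train[0].half_duration_ms
                entry["last_train_half_duration_ms"] = train[-1].half_duration_ms
            entry["afterdischarge"] = afterdischarge_summary(
                evs, stimulus_end_ms, window_ms=window_ms).to_dict()
        out["sites"][site] = entry

    if stimulus_end_ms is not None and ts.sites:
        focus = ts.sites[-1]
        out["afterdischarge"] = out["sites"][focus]["afterdischarge"]
        out["afterdischarge_site"] = focus

    if len(ts.sites) > 1:
        ordering = latency_order(ts)
        def _split(pred):
            return [g["order"] for g in ordering["groups"]
                    if g["times"] and pred(min(g["times"].values()))]
        if stimulus_end_ms is not None:
            out["order_during_train"] = _split(lambda t: t <= stimulus_end_ms)
            out["order_after_train"] = _split(lambda t: t > stimulus_end_ms)
        out["unmatched_events"] = ordering["unmatched"]
    return out


def run_panel(preset_name: str, out_dir, kinetics: str = "generic",
              dt_ms: float | None = None, t_post_ms: float | None = None,
              model_config: Mapping | None = None,
              write_hdf5: bool = True) -> dict:
    """Simulate one preset and write traces + analysis + manifest.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``).
    """
    prot = preset(preset_name)
    if dt_ms is not None:
        prot = prot.with_(dt_ms=dt_ms)
    if t_post_ms is not None:
        prot = prot.with_(t_post_ms=t_post_ms)
    profile = load_profile(kinetics)  # fails fast if the slot is unpopulated

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = _time.time()

    model = build_mossy_fiber(model_config)
    ts = run(model, prot, profile=profile)
    summary = analyze_traceset(ts)

    paths = {"traces_csv": out_dir / f"{preset_name}_traces.csv"}
    ts.to_csv(paths["traces_csv"])
    if write_hdf5:
        paths["traces_h5"] = out_dir / f"{preset_name}_traces.h5"
        ts.to_hdf5(paths["traces_h5"])
    paths["analysis"] = out_dir / f"{preset_name}_analysis.json"
    paths["analysis"].write_text(json.dumps(summary, indent=1, sort_keys=True))

    manifest = {
        "preset": preset_name,
        "protocol": prot.to_dict(),
        "kinetics_profile": profile["name"],
        "model_config_override": dict(model_config) if model_config else None,
        "package_version": __version__,
        "n_segments": model.n_segments,
        "dt_ms": prot.dt_ms,
        "afterdischarge": summary.get("afterdischarge"),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in paths.items()},
        "started_unix": t_start,
        "finished_unix": _time.time(),
    }
    (out_dir / f"{preset_name}_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ------------------------------------------------------------------- sweep

#: grid keys accepted by :func:`sweep` -> Protocol field (zone is special)
_SWEEP_FIELDS = {
    "n_pulses": "n_pulses",
    "frequency_hz": "frequency_hz",
    "el_target_mv": "el_target_mv",
    "variant": "variant",
    "mixture_fraction": "mixture_fraction",
    "g_na_ms_cm2": "g_na_ms_cm2",
    "zone": None,
}


def sweep(grid: Mapping[str, Sequence], base: str | Protocol = "fig1b",
          kinetics: str = "generic", out_csv=None,
          model_config: Mapping | None = None) -> pd.DataFrame:
    """Afterdischarge presence/frequency over a parameter grid.

    ``grid`` maps protocol fields (``n_pulses``, ``frequency_hz``,
    ``el_target_mv``, ``zone`` [named: distal/middle/proximal/uniform],
    ``variant``, ``mixture_fraction``, ``g_na_ms_cm2``) to value lists; the
    Cartesian product is evaluated in deterministic (sorted-key, input-value)
    order.  If ``out_csv`` exists, rows already present are not recomputed
    (resume).  Per-point failures are recorded in the ``error`` column and
    the sweep continues.
    """
    unknown = set(grid) - set(_SWEEP_FIELDS)
    if unknown:
        raise KeyError(f"unknown sweep field(s): {sorted(unknown)}")
    keys_cols = sorted(grid) + ["present", "n_post_spikes", "frequency_hz", "error"]
    if not grid:
        df = pd.DataFrame(columns=keys_cols)
        if out_csv is not None:
            df.to_csv(out_csv, index=False)
        return df
    base_prot = preset(base) if isinstance(base, str) else base
    profile = load_profile(kinetics)
    model = build_mossy_fiber(model_config)

    keys = sorted(grid)
    done: dict = {}
    if out_csv is not None and Path(out_csv).exists():
        prev = pd.read_csv(out_csv)
        if set(keys) <= set(prev.columns):
            for _, row in prev.iterrows():
                done[tuple(row[k] for k in keys)] = row.to_dict()

    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        key = tuple(combo)
        if key in done:
            rows.append(done[key])
            continue
        kw = {}
        for k, v in zip(keys, combo):
            if k == "zone":
                kw["zone"] = ZONES[v] if isinstance(v, str) else tuple(v)
            else:
                kw[k] = v
        row = dict(zip(keys, combo))
        try:
            prot = base_prot.with_(**kw)
            ts = run(model, prot, profile=profile)
            evs = detect_spikes(ts.time_ms, ts[ts.sites[-1]])
            summ = afterdischarge_summary(evs, prot.train_end_ms,
                                          window_ms=prot.t_post_ms)
            row.update(present=summ.present, n_post_spikes=summ.n_spikes,
                       frequency_hz=summ.frequency_hz, error="")
        except Exception as exc:  # per-point failure: record, continue
            row.update(present=None, n_post_spikes=None,
                       frequency_hz=None, error=f"{type(exc).__name__}: {exc}")
        rows.append(row)

    cols = keys + ["present", "n_post_spikes", "frequency_hz", "error"]
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
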