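"""Quantitative readouts from membrane-potential traces.

Operations: threshold-based spike detection, half-duration (width at half
amplitude above a pre-spike baseline), afterdischarge statistics (persistent
firing after the end of a stimulus train), dV/dt traces and rising-phase
peak counting (the IS-SD inflection signature of antidromic somatic spikes),
and cross-site latency ordering (orthodromic vs antidromic propagation).

Detection conventions (the published traces come with none, so these are the
package's):

* spike threshold -20 mV, refractory 2 ms — above all depolarized baselines
  used (>= -60 mV), below all spike peaks;
* baseline of a spike = minimum V in the 5 ms before the threshold crossing,
  so broadened late-train spikes riding on depolarization are measured
  consistently;
* afterdischarge present = at least 3 spikes later than 50 ms after the end
  of the last pulse (excludes a single rebound spike);
* afterdischarge frequency = (N - 1) / (t_last - t_first) over the
  post-stimulus spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .traces import TraceSet

__all__ = [
    "SpikeEvent",
    "AfterdischargeSummary",
    "detect_spikes",
    "half_duration",
    "annotate_half_durations",
    "afterdischarge_summary",
    "derivative_trace",
    "rising_phase_dvdt_peaks",
    "latency_order",
]

DEFAULT_THRESHOLD_MV = -20.0
DEFAULT_REFRACTORY_MS = 2.0
BASELINE_WINDOW_MS = 5.0
AFTERDISCHARGE_GUARD_MS = 50.0
AFTERDISCHARGE_MIN_SPIKES = 3


@dataclass
class SpikeEvent:
    """One detected action potential."""

    t_cross_ms: float      # interpolated upward threshold crossing
    t_peak_ms: float
    v_peak_mv: float
    v_baseline_mv: float
    half_duration_ms: float = float("nan")
    index_cross: int = 0   # sample index of the first suprathreshold sample
    index_peak: int = 0
    flags: tuple = ()

    @property
    def amplitude_mv(self) -> float:
        return self.v_peak_mv - self.v_baseline_mv


@dataclass
class AfterdischargeSummary:
    present: bool
    n_spikes: int
    first_spike_ms: float | None
    last_spike_ms: float | None
    frequency_hz: float | None

    def to_dict(self) -> dict:
        return {
            "present": self.present,
            "n_spikes": self.n_spikes,
            "first_spike_ms": self.first_spike_ms,
            "last_spike_ms": self.last_spike_ms,
            "frequency_hz": self.frequency_hz,
        }


def detect_spikes(time_ms: np.ndarray, v_mv: np.ndarray,
                  threshold_mv: float = DEFAULT_THRESHOLD_MV,
                  refractory_ms: float = DEFAULT_REFRACTORY_MS
                  ) -> list:
    """Upward threshold crossings separated by at least the refractory time.

    The peak of each event is the maximum between the upward crossing and
    the subsequent downward crossing (or the end of the trace); the baseline
    is the minimum V in the 5 ms before the crossing.  Returns an empty list
    when nothing crosses threshold.  Raising the threshold can only remove
    events, never add them.
    """
    t = np.asarray(time_ms, float)
    v = np.asarray(v_mv, float)
    if t.size < 2:
        return []
    dt = t[1] - t[0]

    above = v >= threshold_mv
    up = np.where(~above[:-1] & above[1:])[0] + 1  # first suprathreshold sample
    events: list = []
    last_cross = -np.inf
    for i in up:
        # interpolated crossing time
        frac = (threshold_mv - v[i - 1]) / (v[i] - v[i - 1])
        t_cross = t[i - 1] + frac * dt
        if t_cross - last_cross < refractory_ms:
            continue
        last_cross = t_cross
        # downward crossing
        below = np.where(~above[i:])[0]
        j_end = i + below[0] if below.size else v.size  # exclusive
        seg = slice(i, j_end)
        k_peak = i + int(np.argmax(v[seg]))
        # baseline: minimum over the 5 ms before the crossing
        b0 = max(0, i - int(round(BASELINE_WINDOW_MS / dt)) - 1)
        v_base = float(np.min(v[b0:i])) if i > b0 else float(v[i - 1])
        events.append(SpikeEvent(
            t_cross_ms=float(t_cross),
            t_peak_ms=float(t[k_peak]),
            v_peak_mv=float(v[k_peak]),
            v_baseline_mv=v_base,
            index_cross=int(i),
            index_peak=int(k_peak),
        ))
    return events


def _interp_crossing(t0, v0, t1, v1, level):
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def half_duration(time_ms: np.ndarray, v_mv: np.ndarray, event: SpikeEvent,
                  t_limit_ms: float | None = None) -> float:
    """Spike width (ms) at baseline + 0.5 * (peak - baseline).

    Both flanks are located by walking outward from the peak and linearly
    interpolating between samples.  If the falling flank never returns to
    the half level before ``t_limit_ms`` (e.g. the next event) or the end of
    the trace, the width is undefined and NaN is returned (the caller sees
    the condition flagged on the event).

    Invariant under any affine transform V -> aV + b with a > 0.
    """
    t = np.asarray(time_ms, float)
    v = np.asarray(v_mv, float)
    level = event.v_baseline_mv + 0.5 * (event.v_peak_mv - event.v_baseline_mv)
    k = event.index_peak

    # rising flank: walk left from the peak
    i = k
    while i > 0 and v[i - 1] >= level:
        i -= 1
    if i == 0 and v[0] >= level:
        event.flags = tuple(set(event.flags) | {"rising_flank_truncated"})
        return float("nan")
    t_rise = _interp_crossing(t[i - 1], v[i - 1], t[i], v[i], level)

    # falling flank: walk right
    j_max = v.size - 1
    if t_limit_ms is not None:
        j_max = min(j_max, int(np.searchsorted(t, t_limit_ms)))
    j = k
    while j < j_max and v[j + 1] >= level:
        j += 1
    if j >= j_max or v[j + 1] >= level:
        event.flags = tuple(set(event.flags) | {"falling_flank_undefined"})
        return float("nan")
    t_fall = _interp_crossing(t[j], v[j], t[j + 1], v[j + 1], level)
    return float(t_fall - t_rise)


def annotate_half_durations(time_ms, v_mv, events: Sequence[SpikeEvent]) -> list:
    """Fill ``half_duration_ms`` of each event in place (and return them).

    The falling flank of each spike is bounded by the next event's threshold
    crossing.
    """
    for n, ev in enumerate(events):
        limit = events[n + 1].t_cross_ms if n + 1 < len(events) else None
        ev.half_duration_ms = half_duration(time_ms, v_mv, ev, t_limit_ms=limit)
    return list(events)


def afterdischarge_summary(events: Sequence[SpikeEvent],
                           stimulus_end_ms: float,
                           window_ms: float = 2000.0,
                           presence_min: int = AFTERDISCHARGE_MIN_SPIKES,
                           guard_ms: float = AFTERDISCHARGE_GUARD_MS
                           ) -> AfterdischargeSummary:
    """Post-stimulus firing statistics.

    Counts spikes with peak time in
    (stimulus_end + guard, stimulus_end + window]; presence requires at
    least ``presence_min`` of them.  The frequency (N-1)/span is defined
    only for N >= 2.  Spikes before the stimulus end never affect the
    result.
    """
    t0 = stimulus_end_ms + guard_ms
    t1 = stimulus_end_ms + window_ms
    post = [ev.t_peak_ms for ev in events if t0 < ev.t_peak_ms <= t1]
    n = len(post)
    freq = None
    if n >= 2 and post[-1] > post[0]:
        freq = (n - 1) / (post[-1] - post[0]) * 1000.0
    return AfterdischargeSummary(
        present=n >= presence_min,
        n_spikes=n,
        first_spike_ms=post[0] if post else None,
        last_spike_ms=post[-1] if post else None,
        frequency_hz=freq,
    )


def derivative_trace(time_ms: np.ndarray, v_mv: np.ndarray) -> np.ndarray:
    """dV/dt in mV/ms: central differences inside, one-sided at the ends."""
    return np.gradient(np.asarray(v_mv, float), np.asarray(time_ms, float))


def rising_phase_dvdt_peaks(time_ms, v_mv, event: SpikeEvent,
                            prominence_mv_per_ms: float = 5.0) -> int:
    """Number of prominent dV/dt maxima between threshold crossing and peak.

    Two or more indicates an IS-SD inflection: the initial-segment spike
    arrives before the somatodendritic compartment fires, the signature of
    antidromic invasion of the soma.  Meant for traces sampled at 0.01 ms.
    """
    dvdt = derivative_trace(time_ms, v_mv)
    lo = max(0, event.index_cross - 1)
    hi = event.index_peak + 1
    seg = dvdt[lo:hi + 1]
    peaks, _ = find_peaks(seg, prominence=prominence_mv_per_ms)
    return int(peaks.size)


def latency_order(traceset: TraceSet, sites: Sequence[str] | None = None,
                  window_ms: float = 5.0,
                  threshold_mv: float = DEFAULT_THRESHOLD_MV,
                  refractory_ms: float = DEFAULT_REFRACTORY_MS) -> dict:
    """Match spikes across sites and order the sites by peak time.

    Events are grouped around the first listed site's spikes: for each of
    its events, the nearest event (by peak time, within ``window_ms``) of
    every other site joins the group.  When two candidates are equidistant
    the earlier one is taken and the group is flagged ``"tie"``; groups in
    which all matched peaks coincide exactly fall back to the input site
    order and are flagged as ties as well.  Events that match no group are
    reported separately per site (propagation failures).

    Returns
    -------
    dict with keys
        ``groups`` : list of {"times": {site: t_peak}, "order": [site, ...],
        "flags": [...]}
        ``unmatched`` : {site: [t_peak, ...]}
    """
    sites = list(sites) if sites is not None else traceset.sites
    per_site = {}
    for s in sites:
        evs = detect_spikes(traceset.time_ms, traceset[s],
                            threshold_mv, refractory_ms)
        per_site[s] = [ev.t_peak_ms for ev in evs]

    anchor = sites[0]
    used = {s: np.zeros(len(per_site[s]), bool) for s in sites}
    groups = []
    for a_i, t_a in enumerate(per_site[anchor]):
        times = {anchor: t_a}
        flags = set()
        used[anchor][a_i] = True
        for s in sites[1:]:
            cand = [(abs(tp - t_a), tp, j) for j, tp in enumerate(per_site[s])
                    if not used[s][j] and abs(tp - t_a) <= window_ms]
            if not cand:
                continue
            cand.sort(key=lambda c: (c[0], c[1]))
            if len(cand) > 1 and cand[0][0] == cand[1][0]:
                flags.add("tie")
            _, tp, j = cand[0]
            used[s][j] = True
            times[s] = tp
        order = sorted(times, key=lambda s: (times[s], sites.index(s)))
        if len(set(times.values())) < len(times):
            flags.add("tie")
        groups.append({"times": times, "order": order, "flags": sorted(flags)})

    unmatched = {
        s: [tp for j, tp in enumerate(per_site[s]) if not used[s][j]]
        for s in sites
    }
    return {"groups": groups, "unmatched": {s: u for s, u in unmatched.items() if u}}
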