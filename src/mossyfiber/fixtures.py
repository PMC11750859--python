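"""Ground-truth-known synthetic inputs for testing analysis and solver code.

Two kinds of oracle are generated, neither requiring a full simulation:

* spike-train voltage traces — a flat baseline plus analytic spike templates
  (triangular, Gaussian, or bi-exponential) at prescribed times, with
  optional seeded Gaussian noise.  The generator returns the exact per-spike
  truth (time, peak, half-width) computed from the template's closed form,
  never measured from the trace.
* passive references — the isopotential RC step response with
  tau_m = R_m * C_m, and the sealed-end finite-cable steady-state
  attenuation cosh((L-x)/lambda)/cosh(L/lambda) with
  lambda = sqrt(R_m d / (4 R_i)).

All randomness in the package lives here and is seed-controlled; the cable
solver itself is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .traces import TraceSet

__all__ = [
    "FixtureSpec",
    "make_spike_train_trace",
    "make_passive_references",
    "PassiveReferences",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic spike-train trace."""

    baseline_mv: float = -80.0
    spike_times_ms: tuple = ()
    template: str = "gaussian"      # triangular | gaussian | biexponential
    amplitude_mv: float = 100.0
    # width parameter: gaussian -> sigma (ms); triangular -> total base width
    # (ms); biexponential -> (tau_rise, tau_decay) in ms
    width_ms: float = 0.5
    tau_rise_ms: float = 0.2
    tau_decay_ms: float = 1.0
    dt_ms: float = 0.1
    duration_ms: float = 100.0
    noise_sd_mv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for ts in self.spike_times_ms:
            if not (0.0 <= ts < self.duration_ms):
                raise ValueError(f"spike time {ts} outside [0, duration)")
        if self.template not in ("triangular", "gaussian", "biexponential"):
            raise ValueError(f"unknown template {self.template!r}")
        if self.amplitude_mv <= 0 or self.width_ms <= 0 or self.dt_ms <= 0:
            raise ValueError("amplitude, width and dt must be positive")


def _template_waveform(spec: FixtureSpec, tau: np.ndarray) -> np.ndarray:
    """Template evaluated at times relative to the spike peak (peak = 1)."""
    if spec.template == "gaussian":
        return np.exp(-0.5 * (tau / spec.width_ms) ** 2)
    if spec.template == "triangular":
        half_base = spec.width_ms / 2.0
        return np.clip(1.0 - np.abs(tau) / half_base, 0.0, None)
    # bi-exponential, shifted and normalized so the peak is 1 at tau = 0
    tr, td = spec.tau_rise_ms, spec.tau_decay_ms
    t_peak = math.log(td / tr) * tr * td / (td - tr)
    norm = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    s = tau + t_peak
    out = np.where(s > 0, np.exp(-s / td) - np.exp(-s / tr), 0.0) / norm
    return out


def _template_half_width(spec: FixtureSpec) -> float:
    """Closed-form full width at half maximum of the template."""
    if spec.template == "gaussian":
        return GAUSSIAN_FWHM_FACTOR * spec.width_ms
    if spec.template == "triangular":
        return spec.width_ms / 2.0
    tr, td = spec.tau_rise_ms, spec.tau_decay_ms
    t_peak = math.log(td / tr) * tr * td / (td - tr)
    norm = math.exp(-t_peak / td) - math.exp(-t_peak / tr)

    def f(s):
        return (math.exp(-s / td) - math.exp(-s / tr)) / norm - 0.5

    left = brentq(f, 1e-12, t_peak)
    right = brentq(f, t_peak, t_peak + 50.0 * td)
    return right - left


def make_spike_train_trace(spec: FixtureSpec):
    """Build the trace and its exact truth table.

    Returns
    -------
    (TraceSet, DataFrame)
        One-site trace set (site label ``"fixture"``) and a truth table with
        columns ``t_spike_ms``, ``v_peak_mv``, ``half_width_ms``,
        ``overlap`` (True when the neighbouring spike is closer than one
        template half-width — metrics on such spikes are not guaranteed).
    """
    n = int(round(spec.duration_ms / spec.dt_ms)) + 1
    t = np.arange(n) * spec.dt_ms
    v = np.full(n, spec.baseline_mv)
    for ts in spec.spike_times_ms:
        v += spec.amplitude_mv * _template_waveform(spec, t - ts)
    if spec.noise_sd_mv > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd_mv, size=n)

    hw = _template_half_width(spec)
    times = np.asarray(sorted(spec.spike_times_ms), float)
    gaps = np.diff(times)
    overlap = np.zeros(times.size, bool)
    if gaps.size:
        close = gaps < hw
        overlap[:-1] |= close
        overlap[1:] |= close
    truth = pd.DataFrame({
        "t_spike_ms": times,
        "v_peak_mv": spec.baseline_mv + spec.amplitude_mv,
        "half_width_ms": hw,
        "overlap": overlap,
    })
    trace = TraceSet(
        time_ms=t, data={"fixture": v}, dt_ms=spec.dt_ms,
        meta={"fixture_spec": {
            "template": spec.template, "baseline_mv": spec.baseline_mv,
            "amplitude_mv": spec.amplitude_mv, "seed": spec.seed,
            "noise_sd_mv": spec.noise_sd_mv,
        }},
    )
    return trace, truth


@dataclass(frozen=True)
class PassiveReferences:
    """Analytic passive oracles for the cable solver."""

    r_m_ohm_cm2: float = 10_000.0
    c_m_uf_cm2: float = 1.0
    r_i_ohm_cm: float = 110.0
    diameter_um: float = 0.2

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant R_m * C_m (10 ms at the defaults)."""
        return self.r_m_ohm_cm2 * self.c_m_uf_cm2 * 1e-3

    @property
    def lambda_um(self) -> float:
        """Steady-state space constant sqrt(R_m d / (4 R_i))."""
        d_cm = self.diameter_um * 1e-4
        lam_cm = math.sqrt(self.r_m_ohm_cm2 * d_cm / (4.0 * self.r_i_ohm_cm))
        return lam_cm * 1e4

    def rc_step_response(self, t_ms, v0_mv: float, i_inj_na: float,
                         area_cm2: float) -> np.ndarray:
        """V(t) of an isopotential patch of the given area under a current
        step: V0 + I R (1 - exp(-t/tau_m)), R = R_m / area."""
        t = np.asarray(t_ms, float)
        r_mohm = self.r_m_ohm_cm2 / area_cm2 * 1e-6  # Ohm -> MOhm
        dv = i_inj_na * r_mohm  # nA * MOhm = mV
        return v0_mv + dv * (1.0 - np.exp(-t / self.tau_m_ms))

    def cable_attenuation(self, x_um, cable_length_um: float) -> np.ndarray:
        """Sealed-end steady-state attenuation cosh((L-x)/lam)/cosh(L/lam)
        for a cable held at x = 0 (1 exactly at x = 0; -> exp(-x/lam) as
        L -> infinity)."""
        lam = self.lambda_um
        x = np.asarray(x_um, float)
        L = cable_length_um
        # cosh((L-x)/lam)/cosh(L/lam), computed in log space for large L/lam
        a = (L - x) / lam
        b = L / lam
        return np.exp(a - b) * (1.0 + np.exp(-2.0 * a)) / (1.0 + np.exp(-2.0 * b))


def make_passive_references(r_m_ohm_cm2: float = 10_000.0,
                            c_m_uf_cm2: float = 1.0,
                            r_i_ohm_cm: float = 110.0,
                            diameter_um: float = 0.2) -> PassiveReferences:
    return PassiveReferences(r_m_ohm_cm2, c_m_uf_cm2, r_i_ohm_cm, diameter_um)
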