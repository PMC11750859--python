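"""Stimulation protocols and the named presets for every simulated panel.

A :class:`Protocol` bundles the somatic current train (amplitude, width,
frequency, count), an optional local depolarization zone (landmark names +
target leak reversal), the K+-channel variant, integration settings and
recording sites.  ``preset(name)`` returns the exact configuration of each
published panel (fig1a..fig1h, fig2, fig3a/c/e/g/i, fig4a..fig4f, fig5a/b).

Zone shorthands (each a bouton plus the axon cylinders on both sides)::

    distal   : bouton_10, axon_10, axon_11
    middle   : bouton_6,  axon_6,  axon_7
    proximal : bouton_2,  axon_2,  axon_3
    uniform  : boutons 2-10 and axons 2-11
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np

from .exceptions import ModelConfigError, UnknownPresetError

__all__ = ["Protocol", "stimulus_current", "preset", "list_presets", "ZONES"]

ZONES: dict = {
    "distal": ("bouton_10", "axon_10", "axon_11"),
    "middle": ("bouton_6", "axon_6", "axon_7"),
    "proximal": ("bouton_2", "axon_2", "axon_3"),
    "uniform": tuple(
        [f"bouton_{k}" for k in range(2, 11)] + [f"axon_{k}" for k in range(2, 12)]
    ),
}

VARIANTS = ("inactivating", "non_inactivating", "mixture")


@dataclass(frozen=True)
class Protocol:
    """One fully-specified simulation experiment (pure data)."""

    name: str = "custom"
    amplitude_na: float = 0.2        # injected pulse amplitude, nA
    pulse_width_ms: float = 2.0
    frequency_hz: float = 50.0
    n_pulses: int = 50
    zone: tuple = ()                 # landmark names to depolarize
    el_target_mv: float | None = None
    variant: str = "inactivating"
    mixture_fraction: float = 0.9    # used only when variant == "mixture"
    g_na_ms_cm2: float | None = None  # axon/bouton Na+ density override
    dt_ms: float = 0.1
    t_pre_ms: float = 200.0          # equilibration before the first pulse
    t_post_ms: float = 2000.0        # observation window after the train
    recording_sites: tuple = ("soma", "bouton_10")
    injection_site: str = "soma"

    def __post_init__(self):
        if self.n_pulses < 0:
            raise ModelConfigError("n_pulses must be >= 0")
        if self.frequency_hz <= 0 or self.pulse_width_ms <= 0:
            raise ModelConfigError("frequency and pulse width must be positive")
        if self.period_ms < self.pulse_width_ms:
            raise ModelConfigError(
                f"pulse period {self.period_ms:.3g} ms shorter than pulse "
                f"width {self.pulse_width_ms:.3g} ms"
            )
        if self.variant not in VARIANTS:
            raise ModelConfigError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.zone and self.el_target_mv is None:
            raise ModelConfigError("zone given without el_target_mv")
        if self.dt_ms <= 0 or self.t_pre_ms < 0 or self.t_post_ms < 0:
            raise ModelConfigError("invalid integration timing")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    @property
    def train_end_ms(self) -> float:
        """End of the last pulse (equals t_pre for an empty train)."""
        if self.n_pulses == 0:
            return self.t_pre_ms
        return self.t_pre_ms + (self.n_pulses - 1) * self.period_ms + self.pulse_width_ms

    @property
    def total_ms(self) -> float:
        return self.train_end_ms + self.t_post_ms

    def to_dict(self) -> dict:
        d = asdict(self)
        d["zone"] = list(self.zone)
        d["recording_sites"] = list(self.recording_sites)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Protocol":
        d = dict(d)
        d["zone"] = tuple(d.get("zone", ()))
        d["recording_sites"] = tuple(d.get("recording_sites", ("soma",)))
        return cls(**d)

    def with_(self, **kw) -> "Protocol":
        return replace(self, **kw)


def stimulus_current(protocol: Protocol, t_ms):
    """Injected current (nA) at time(s) ``t_ms``.

    The k-th pulse occupies the half-open window
    [t_pre + k*period, t_pre + k*period + width), k = 0..n_pulses-1.
    """
    t = np.asarray(t_ms, dtype=float)
    if protocol.n_pulses == 0:
        return np.zeros_like(t)
    rel = t - protocol.t_pre_ms
    k = np.floor(rel / protocol.period_ms)
    in_train = (rel >= 0) & (k <= protocol.n_pulses - 1)
    phase = rel - k * protocol.period_ms
    on = in_train & (phase < protocol.pulse_width_ms)
    return np.where(on, protocol.amplitude_na, 0.0)


# ---------------------------------------------------------------------------
# Preset table

_FAST = {"dt_ms": 0.01}
_D70 = {"zone": ZONES["distal"], "el_target_mv": -70.0}
_D60 = {"zone": ZONES["distal"], "el_target_mv": -60.0}

_PRESETS: dict = {
    # Induction of afterdischarge vs stimulus count/frequency (panels 1A-1H)
    "fig1a": dict(frequency_hz=50, n_pulses=50),
    "fig1b": dict(frequency_hz=50, n_pulses=50, **_D70),
    "fig1c": dict(frequency_hz=50, n_pulses=40, **_D70),
    "fig1d": dict(frequency_hz=20, n_pulses=60, **_D70),
    "fig1e": dict(frequency_hz=20, n_pulses=50, **_D70),
    "fig1f": dict(frequency_hz=100, n_pulses=50, **_D70),
    "fig1g": dict(frequency_hz=100, n_pulses=40, **_D70),
    "fig1h": dict(frequency_hz=100, n_pulses=50, g_na_ms_cm2=60.0, **_D70),
    # Antidromic propagation / dV/dt kinetics: fig1b at 100 kHz sampling
    "fig2": dict(frequency_hz=50, n_pulses=50, **_D70, **_FAST),
    # K+-channel inactivation dependence
    "fig3a": dict(frequency_hz=50, n_pulses=50, **_D70),
    "fig3c": dict(frequency_hz=50, n_pulses=50, variant="non_inactivating", **_D70),
    "fig3e": dict(frequency_hz=50, n_pulses=50, variant="mixture",
                  mixture_fraction=0.9, **_D70),
    "fig3g": dict(frequency_hz=50, n_pulses=50, variant="mixture",
                  mixture_fraction=0.9, **_D60),
    "fig3i": dict(frequency_hz=50, n_pulses=100, variant="non_inactivating", **_D60),
    # Location of the depolarized zone
    "fig4a": dict(frequency_hz=50, n_pulses=50, **_D70),
    "fig4b": dict(frequency_hz=50, n_pulses=50, zone=ZONES["middle"],
                  el_target_mv=-70.0),
    "fig4c": dict(frequency_hz=50, n_pulses=50, zone=ZONES["middle"],
                  el_target_mv=-60.0),
    "fig4d": dict(frequency_hz=50, n_pulses=50, zone=ZONES["proximal"],
                  el_target_mv=-70.0),
    "fig4e": dict(frequency_hz=50, n_pulses=50, zone=ZONES["proximal"],
                  el_target_mv=-60.0),
    "fig4f": dict(frequency_hz=50, n_pulses=50, zone=ZONES["uniform"],
                  el_target_mv=-75.0),
    # Bi-directional propagation from a mid-axon ectopic site
    "fig5a": dict(frequency_hz=50, n_pulses=50, zone=ZONES["middle"],
                  el_target_mv=-70.0,
                  recording_sites=("soma", "bouton_6", "bouton_10")),
    "fig5b": dict(frequency_hz=50, n_pulses=50, zone=ZONES["middle"],
                  el_target_mv=-60.0,
                  recording_sites=("soma", "bouton_6", "bouton_10")),
}

_DESCRIPTIONS: dict = {
    "fig1a": "50 Hz x 50, rest -80 mV everywhere (no afterdischarge)",
    "fig1b": "50 Hz x 50, distal zone at -70 mV (afterdischarge)",
    "fig1c": "50 Hz x 40, distal -70 mV (below pulse-count threshold)",
    "fig1d": "20 Hz x 60, distal -70 mV (afterdischarge)",
    "fig1e": "20 Hz x 50, distal -70 mV (below threshold)",
    "fig1f": "100 Hz x 50, distal -70 mV (afterdischarge)",
    "fig1g": "100 Hz x 40, distal -70 mV (below threshold)",
    "fig1h": "100 Hz x 50, distal -70 mV, g_Na 50->60 mS/cm2",
    "fig2": "fig1b at dt = 0.01 ms for dV/dt analysis",
    "fig3a": "inactivating K+, 50 Hz x 50, distal -70 mV",
    "fig3c": "non-inactivating K+, same stimulus (no afterdischarge)",
    "fig3e": "90/10 inactivating/non-inactivating mixture, distal -70 mV",
    "fig3g": "90/10 mixture, distal -60 mV",
    "fig3i": "non-inactivating K+, 50 Hz x 100, distal -60 mV",
    "fig4a": "distal zone -70 mV (same as fig1b)",
    "fig4b": "middle zone -70 mV",
    "fig4c": "middle zone -60 mV",
    "fig4d": "proximal zone -70 mV",
    "fig4e": "proximal zone -60 mV",
    "fig4f": "uniform zone (boutons 2-10 + flanking axons) -75 mV",
    "fig5a": "middle zone -70 mV, three recording sites",
    "fig5b": "middle zone -60 mV, three recording sites",
}


def preset(name: str) -> Protocol:
    """The exact protocol of a named panel (pure data; repeatable)."""
    try:
        kw = _PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
    return Protocol(name=name, **kw)


def list_presets() -> dict:
    """Mapping preset name -> one-line description."""
    return dict(_DESCRIPTIONS)
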