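"""Declarative Hodgkin-Huxley channel definitions and gate-rate evaluation.

Channels are *data*: each gate is parameterized by closed-form rate families
(or a tabulated curve), so a kinetics profile is a YAML tree and different
rate sets (e.g. constants transcribed from a published model deposit) drop in
without code changes.  A gate may be given either as forward/backward rates
``alpha(V)``, ``beta(V)`` (then ``x_inf = a/(a+b)``, ``tau = 1/(a+b)``) or
directly as ``x_inf(V)`` and ``tau(V)``.

Rate families (V in mV, rates in 1/ms, tau in ms)::

    exponential        A * exp((V - V0) / k)
    sigmoid            A / (1 + exp(-(V - V0) / k))
    linoid             A * (V - V0) / (1 - exp(-(V - V0) / k))
                       (removable singularity at V = V0: limit A*k)
    constant           value
    const_plus_sigmoid base + amp / (1 + exp((V - V0) / k))    (tau only)
    table              linear interpolation on a (v, y) grid

The shipped ``generic`` profile contains a squid-type Na+ (m^3 h) and
delayed-rectifier K+ (n^4) shifted to a -80 mV resting potential, plus a
Kv1.4-style inactivation gate (slow h on the K+ channel: inactivates over
tens of ms at spike potentials, recovers over hundreds of ms at rest), which
is what produces cumulative K+-channel inactivation and use-dependent spike
broadening during repetitive firing.  The ``paper`` profile is an
intentionally empty slot for rate constants transcribed from the ModelDB
deposits the mossy-fiber model is built from (see ``profiles/paper.yaml``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    KineticsProfileUnavailable,
    ModelConfigError,
    UnknownChannelError,
)

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "eval_rate",
    "eval_gate",
    "channel_current_density",
    "steady_state_gates",
    "make_variant",
    "gate_timecourse",
    "tabulate_gate",
    "gate_from_table",
    "load_profile",
    "list_profiles",
]

DEFAULT_GK_MS_CM2 = 36.0
_RATE_FAMILIES = ("exponential", "sigmoid", "linoid", "constant",
                  "const_plus_sigmoid", "table")


def eval_rate(spec: Mapping, V):
    """Evaluate one rate/curve parameterization at voltage(s) ``V`` (mV)."""
    V = np.asarray(V, dtype=float)
    fam = spec.get("family")
    if fam == "exponential":
        return spec["A"] * np.exp((V - spec["V0"]) / spec["k"])
    if fam == "sigmoid":
        return spec.get("A", 1.0) / (1.0 + np.exp(-(V - spec["V0"]) / spec["k"]))
    if fam == "linoid":
        A, V0, k = spec["A"], spec["V0"], spec["k"]
        y = (V - V0) / k
        # A*k*y/(1-exp(-y)); limit A*k at y -> 0
        with np.errstate(over="ignore"):
            denom = -np.expm1(-y)
        small = np.abs(y) < 1e-7
        out = np.where(small, A * k * (1.0 + y / 2.0),
                       A * k * y / np.where(small, 1.0, denom))
        return out
    if fam == "constant":
        return np.full_like(V, float(spec["value"]))
    if fam == "const_plus_sigmoid":
        return spec["base"] + spec["amp"] / (
            1.0 + np.exp((V - spec["V0"]) / spec["k"])
        )
    if fam == "table":
        return np.interp(V, np.asarray(spec["v"], float), np.asarray(spec["y"], float))
    raise ModelConfigError(f"unknown rate family {fam!r}")


@dataclass(frozen=True)
class GateSpec:
    """One gating variable (m, h, n, ...) of an HH-style channel.

    Exactly one of the two parameterizations must be supplied:

    * ``alpha`` and ``beta`` rate specs, or
    * ``xinf`` and ``tau`` curve specs.
    """

    name: str
    exponent: int = 1
    alpha: Mapping | None = None
    beta: Mapping | None = None
    xinf: Mapping | None = None
    tau: Mapping | None = None

    def __post_init__(self):
        if self.exponent < 1:
            raise ModelConfigError(f"gate {self.name!r}: exponent must be >= 1")
        ab = self.alpha is not None and self.beta is not None
        xt = self.xinf is not None and self.tau is not None
        if ab == xt:
            raise ModelConfigError(
                f"gate {self.name!r}: define either (alpha, beta) or (xinf, tau)"
            )


def eval_gate(gate: GateSpec, V):
    """Steady state and time constant of a gate at voltage(s) ``V``.

    Returns
    -------
    (x_inf, tau_ms) : tuple of ndarray (or scalars)
        ``0 <= x_inf <= 1`` and ``tau > 0`` over the physiological range.
    """
    if gate.alpha is not None:
        a = eval_rate(gate.alpha, V)
        b = eval_rate(gate.beta, V)
        s = a + b
        return a / s, 1.0 / s
    return eval_rate(gate.xinf, V), eval_rate(gate.tau, V)


@dataclass(frozen=True)
class ChannelSpec:
    """A conductance with HH gates (gates empty for an ohmic leak).

    ``g_ms_cm2`` is the channel's full conductance density; when the channel
    is one component of a K+ mixture, ``fraction`` scales the per-segment
    density map it draws from (so a 90/10 mixture conserves total density
    exactly).  ``density_key`` names the morphology density map ("na"/"k")
    the channel is placed by.
    """

    label: str
    g_ms_cm2: float
    reversal_mv: float
    gates: tuple = ()
    density_key: str = ""
    fraction: float = 1.0

    def __post_init__(self):
        if self.g_ms_cm2 < 0:
            raise ModelConfigError(f"channel {self.label!r}: negative conductance")
        if not (0.0 <= self.fraction <= 1.0):
            raise ModelConfigError(f"channel {self.label!r}: fraction outside [0,1]")
        if not self.density_key:
            object.__setattr__(self, "density_key", self.label.split("_")[0])

    def open_fraction(self, gate_values: Mapping[str, float]):
        out = 1.0
        for g in self.gates:
            out = out * np.asarray(gate_values[g.name]) ** g.exponent
        return out


def channel_current_density(
    channel: ChannelSpec, V, gate_values: Mapping[str, float]
) -> float:
    """Ohmic HH current density g * prod(x^p) * (V - E), in uA/cm^2.

    mS/cm^2 times mV gives uA/cm^2 directly; the current is exactly zero at
    the reversal potential regardless of gate state.
    """
    V = np.asarray(V, dtype=float)
    return channel.g_ms_cm2 * channel.open_fraction(gate_values) * (V - channel.reversal_mv)


def steady_state_gates(channels: Iterable[ChannelSpec], V) -> dict:
    """Every gate set to its x_inf(V); idempotent by construction."""
    out = {}
    for ch in channels:
        out[ch.label] = {g.name: eval_gate(g, V)[0] for g in ch.gates}
    return out


def gate_timecourse(gate: GateSpec, t_ms: np.ndarray, v_mv: np.ndarray,
                    x0: float | None = None) -> np.ndarray:
    """Integrate one gate under a prescribed voltage waveform.

    Uses the exact exponential update on each (uniform) step, the same update
    rule as the cable solver.  Useful for voltage-clamp style analyses, e.g.
    tracking available K+ conductance across an action-potential train.
    """
    t_ms = np.asarray(t_ms, float)
    v_mv = np.asarray(v_mv, float)
    dt = t_ms[1] - t_ms[0]
    xinf, tau = eval_gate(gate, v_mv)
    x = np.empty_like(v_mv)
    x[0] = xinf[0] if x0 is None else x0
    decay = np.exp(-dt / tau)
    for i in range(1, x.size):
        x[i] = xinf[i - 1] + (x[i - 1] - xinf[i - 1]) * decay[i - 1]
    return x


# ---------------------------------------------------------------------------
# Profiles and variants


def _gate_from_config(name: str, cfg: Mapping) -> GateSpec:
    return GateSpec(
        name=name,
        exponent=int(cfg.get("exponent", 1)),
        alpha=cfg.get("alpha"),
        beta=cfg.get("beta"),
        xinf=cfg.get("xinf"),
        tau=cfg.get("tau"),
    )


def _channel_from_config(label: str, cfg: Mapping, g_override: float | None = None
                         ) -> ChannelSpec:
    gates = tuple(
        _gate_from_config(n, c) for n, c in cfg.get("gates", {}).items()
    )
    return ChannelSpec(
        label=label,
        g_ms_cm2=float(g_override if g_override is not None
                       else cfg.get("g_ms_cm2", 0.0)),
        reversal_mv=float(cfg["reversal_mv"]),
        gates=gates,
        density_key=cfg.get("density_key", ""),
    )


def _profile_dir() -> Path:
    return Path(importlib.resources.files("mossyfiber")) / "profiles"


def list_profiles() -> list:
    return sorted(p.stem for p in _profile_dir().glob("*.yaml"))


def load_profile(name_or_path: str = "generic") -> dict:
    """Load a kinetics profile (``generic``, ``paper``, or a YAML path).

    Returns a dict with keys ``name``, ``channels`` (label -> raw config) and
    pre-built ``specs`` (label -> :class:`ChannelSpec`).

    Raises
    ------
    KineticsProfileUnavailable
        If the profile file is a declared-but-unpopulated slot (its YAML sets
        ``status: unpopulated``), e.g. the ``paper`` profile awaiting
        transcription of rate constants from ModelDB accession 128079
        (hhmfb.mod, KIn.mod) / the model deposit accession 2018003.
    """
    path = Path(name_or_path)
    if not path.suffix:
        path = _profile_dir() / f"{name_or_path}.yaml"
    if not path.exists():
        raise KineticsProfileUnavailable(
            f"no kinetics profile {name_or_path!r}; available: {list_profiles()}"
        )
    tree = yaml.safe_load(path.read_text())
    if tree.get("status") == "unpopulated":
        raise KineticsProfileUnavailable(
            f"kinetics profile {tree.get('name', path.stem)!r} ({path}) is a "
            "config slot without rate constants. "
            + tree.get("note", "Populate its 'channels' section to use it.")
        )
    channels = tree["channels"]
    specs = {label: _channel_from_config(label, cfg) for label, cfg in channels.items()}
    return {"name": tree.get("name", path.stem), "channels": channels, "specs": specs}


def make_variant(
    kind: str,
    fraction_inactivating: float = 0.9,
    g_k_ms_cm2: float = DEFAULT_GK_MS_CM2,
    profile: Mapping | str = "generic",
) -> tuple:
    """K+-channel variant of the model: pure or mixed inactivation.

    Parameters
    ----------
    kind : {"inactivating", "non_inactivating", "mixture"}
    fraction_inactivating : float in [0, 1]
        Only used for ``mixture``: fraction of the total K+ density carried
        by the inactivating channel (the rest is non-inactivating).
    g_k_ms_cm2 : float
        Total K+ conductance density split between the components.
    profile : str or loaded profile

    Returns
    -------
    tuple of ChannelSpec
        The Na+ channel plus one or two K+ channels whose densities sum to
        ``g_k_ms_cm2`` exactly.
    """
    if isinstance(profile, str):
        profile = load_profile(profile)
    specs = profile["specs"]
    for needed in ("na", "k_inactivating", "k_noninactivating"):
        if needed not in specs:
            raise UnknownChannelError(
                f"profile {profile['name']!r} lacks channel {needed!r}"
            )
    na = specs["na"]
    ki = specs["k_inactivating"]
    kn = specs["k_noninactivating"]

    def scaled(spec: ChannelSpec, frac: float) -> ChannelSpec:
        return ChannelSpec(
            label=spec.label,
            g_ms_cm2=frac * g_k_ms_cm2,
            reversal_mv=spec.reversal_mv,
            gates=spec.gates,
            density_key=spec.density_key,
            fraction=frac,
        )

    if kind == "inactivating":
        return (na, scaled(ki, 1.0))
    if kind == "non_inactivating":
        return (na, scaled(kn, 1.0))
    if kind == "mixture":
        f = float(fraction_inactivating)
        if not (0.0 <= f <= 1.0):
            raise ModelConfigError("fraction_inactivating outside [0, 1]")
        if f == 1.0:
            return (na, scaled(ki, 1.0))
        if f == 0.0:
            return (na, scaled(kn, 1.0))
        return (na, scaled(ki, f), scaled(kn, 1.0 - f))
    raise UnknownChannelError(
        f"unknown variant kind {kind!r}; expected inactivating, "
        "non_inactivating or mixture"
    )


# ---------------------------------------------------------------------------
# Tabulated-curve export / import


def tabulate_gate(gate: GateSpec, v_grid: Sequence[float]) -> pd.DataFrame:
    """x_inf and tau on a voltage grid, as a DataFrame (columns v, xinf, tau)."""
    v = np.asarray(v_grid, float)
    xinf, tau = eval_gate(gate, v)
    return pd.DataFrame({"v": v, "xinf": xinf, "tau": tau})


def gate_from_table(df: pd.DataFrame, name: str, exponent: int = 1) -> GateSpec:
    """Rebuild a gate from a tabulated curve (inverse of :func:`tabulate_gate`)."""
    v = df["v"].to_numpy(float).tolist()
    return GateSpec(
        name=name,
        exponent=exponent,
        xinf={"family": "table", "v": v, "y": df["xinf"].to_numpy(float).tolist()},
        tau={"family": "table", "v": v, "y": df["tau"].to_numpy(float).tolist()},
    )
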