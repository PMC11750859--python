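"""Discretized mossy-fiber morphology.

The hippocampal mossy fiber (the granule-cell axon) is approximated by an
unbranched chain of cylindrical sections: a soma, then eleven thin axonal
cylinders with ten *en passant* boutons interleaved::

    soma - axon_1 - bouton_1 - axon_2 - ... - bouton_10 - axon_11

Each section is split into segments at a fixed spatial density (default
1 segment per micrometre), giving a single global array of compartments on
which the cable equation is integrated.  Landmarks map section names
(``soma``, ``axon_k``, ``bouton_k``) to contiguous global segment-index
ranges, so protocols can address "the 10th bouton and the axons on both
sides" symbolically.

Geometry defaults
-----------------
soma   : cylinder, diameter 10 um, length 10 um (length = diameter)
axon   : cylinder, diameter 0.2 um, length 100 um, 11 of them
bouton : cylinder, diameter 4 um, length 4 um (length = diameter), 10 of them

Boutons have no stated length in the source morphology; a cylinder with
length equal to diameter is used so that its lateral area approximates the
surface of a sphere of the same diameter.  The same convention is applied to
the soma.

Passive defaults: C_m = 1 uF/cm^2, R_m = 10,000 Ohm cm^2, R_i = 110 Ohm cm,
leak reversal e_l = -80 mV everywhere.  Active channel densities: Na+
50 mS/cm^2 on axons and boutons, 10 mS/cm^2 on the soma; K+ 36 mS/cm^2
everywhere; leak conductance 1/R_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ModelConfigError, UnknownLandmarkError, UnknownChannelError

__all__ = [
    "SectionSpec",
    "CellModel",
    "DEFAULT_MODEL_CONFIG",
    "build_mossy_fiber",
    "apply_depolarization_zone",
    "site_index",
]

#: Channels the default morphology knows how to place.
KNOWN_CHANNELS = ("na", "k")

SECTION_KINDS = ("soma", "axon", "bouton")

#: Full default parameter tree; every entry may be overridden via the
#: ``config`` argument of :func:`build_mossy_fiber` (or a YAML file with the
#: same structure, see :mod:`mossyfiber.config`).
DEFAULT_MODEL_CONFIG: dict = {
    "geometry": {
        "soma": {"diameter_um": 10.0, "length_um": 10.0},
        "axon": {"diameter_um": 0.2, "length_um": 100.0, "count": 11},
        "bouton": {"diameter_um": 4.0, "length_um": 4.0, "count": 10},
        "segments_per_um": 1.0,
    },
    "passive": {
        "c_m_uf_cm2": 1.0,
        "r_m_ohm_cm2": 10_000.0,
        "r_i_ohm_cm": 110.0,
        "e_leak_mv": -80.0,
    },
    "densities_ms_cm2": {
        "na": {"soma": 10.0, "axon": 50.0, "bouton": 50.0},
        "k": {"soma": 36.0, "axon": 36.0, "bouton": 36.0},
    },
}


@dataclass(frozen=True)
class SectionSpec:
    """One cylindrical section of the chain.

    Parameters
    ----------
    name : str
        Landmark label, e.g. ``"bouton_10"``.
    kind : {"soma", "axon", "bouton"}
    length_um, diameter_um : float
        Cylinder dimensions in micrometres; must be positive.
    n_segments : int
        Number of equal compartments the section is split into (>= 1).
    c_m_uf_cm2, r_m_ohm_cm2, r_i_ohm_cm : float
        Passive constants.
    e_leak_mv : float
        Leak reversal for every segment of this section (overridable per
        segment at the model level).
    channel_densities : mapping label -> mS/cm^2
    """

    name: str
    kind: str
    length_um: float
    diameter_um: float
    n_segments: int
    c_m_uf_cm2: float = 1.0
    r_m_ohm_cm2: float = 10_000.0
    r_i_ohm_cm: float = 110.0
    e_leak_mv: float = -80.0
    channel_densities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in SECTION_KINDS:
            raise ModelConfigError(f"unknown section kind {self.kind!r}")
        if not (self.length_um > 0 and self.diameter_um > 0):
            raise ModelConfigError(
                f"section {self.name!r}: length and diameter must be positive "
                f"(got L={self.length_um}, d={self.diameter_um})"
            )
        if self.n_segments < 1:
            raise ModelConfigError(
                f"section {self.name!r}: n_segments must be >= 1"
            )
        if self.c_m_uf_cm2 <= 0 or self.r_m_ohm_cm2 <= 0 or self.r_i_ohm_cm <= 0:
            raise ModelConfigError(
                f"section {self.name!r}: passive constants must be positive"
            )
        for g in self.channel_densities.values():
            if g < 0:
                raise ModelConfigError(
                    f"section {self.name!r}: negative channel density"
                )

    @property
    def segment_length_um(self) -> float:
        return self.length_um / self.n_segments

    @property
    def segment_area_cm2(self) -> float:
        """Lateral membrane area of one segment (pi * d * L/n), in cm^2."""
        um2_to_cm2 = 1e-8
        return math.pi * self.diameter_um * self.segment_length_um * um2_to_cm2


def default_n_segments(length_um: float, segments_per_um: float = 1.0) -> int:
    """Default discretization: round(length * density), at least 1 segment."""
    return max(1, round(length_um * segments_per_um))


@dataclass(frozen=True)
class CellModel:
    """The discretized chain, flattened to global per-segment arrays.

    Attributes
    ----------
    sections : tuple of SectionSpec
        Ordered soma -> axon_1 -> bouton_1 -> ... chain.
    landmarks : dict name -> (start, stop)
        Contiguous, disjoint global segment ranges (Python half-open) covering
        all segments, monotone in path distance from the soma.
    seg_length_cm, diameter_cm, area_cm2, c_m, r_m, r_i, e_leak : ndarray
        Per-segment geometry and passive parameters.
    seg_kind : ndarray of str
        Section kind per segment ("soma"/"axon"/"bouton").
    channel_densities : dict label -> ndarray (mS/cm^2 per segment)
    """

    sections: tuple
    landmarks: dict
    seg_length_cm: np.ndarray
    diameter_cm: np.ndarray
    area_cm2: np.ndarray
    c_m: np.ndarray
    r_m: np.ndarray
    r_i: np.ndarray
    e_leak: np.ndarray
    seg_kind: np.ndarray
    channel_densities: dict

    @property
    def n_segments(self) -> int:
        return self.e_leak.size

    @property
    def total_area_cm2(self) -> float:
        return float(self.area_cm2.sum())

    @classmethod
    def from_sections(cls, sections: Iterable[SectionSpec]) -> "CellModel":
        sections = tuple(sections)
        if not sections:
            raise ModelConfigError("cell must contain at least one section")
        names = [s.name for s in sections]
        if len(set(names)) != len(names):
            raise ModelConfigError("duplicate section names")

        landmarks = {}
        seg_len, diam, area, cm, rm, ri, el, kinds = ([] for _ in range(8))
        channels = sorted({ch for s in sections for ch in s.channel_densities})
        dens = {ch: [] for ch in channels}
        start = 0
        for s in sections:
            stop = start + s.n_segments
            landmarks[s.name] = (start, stop)
            seg_len += [s.segment_length_um * 1e-4] * s.n_segments  # um -> cm
            diam += [s.diameter_um * 1e-4] * s.n_segments
            area += [s.segment_area_cm2] * s.n_segments
            cm += [s.c_m_uf_cm2] * s.n_segments
            rm += [s.r_m_ohm_cm2] * s.n_segments
            ri += [s.r_i_ohm_cm] * s.n_segments
            el += [s.e_leak_mv] * s.n_segments
            kinds += [s.kind] * s.n_segments
            for ch in channels:
                dens[ch] += [float(s.channel_densities.get(ch, 0.0))] * s.n_segments
            start = stop

        return cls(
            sections=sections,
            landmarks=landmarks,
            seg_length_cm=np.asarray(seg_len),
            diameter_cm=np.asarray(diam),
            area_cm2=np.asarray(area),
            c_m=np.asarray(cm),
            r_m=np.asarray(rm),
            r_i=np.asarray(ri),
            e_leak=np.asarray(el),
            seg_kind=np.asarray(kinds, dtype=object),
            channel_densities={ch: np.asarray(v) for ch, v in dens.items()},
        )

    # -- landmark helpers -------------------------------------------------

    def landmark_range(self, name: str) -> tuple:
        try:
            return self.landmarks[name]
        except KeyError:
            raise UnknownLandmarkError(
                f"unknown landmark {name!r}; available: {sorted(self.landmarks)}"
            ) from None

    def landmark_slice(self, name: str) -> slice:
        start, stop = self.landmark_range(name)
        return slice(start, stop)

    def with_e_leak(self, e_leak: np.ndarray) -> "CellModel":
        if e_leak.shape != self.e_leak.shape:
            raise ModelConfigError("e_leak array shape mismatch")
        return replace(self, e_leak=np.array(e_leak, dtype=float))

    def with_channel_density(self, label: str, density: np.ndarray) -> "CellModel":
        if label not in self.channel_densities:
            raise UnknownChannelError(label)
        dens = dict(self.channel_densities)
        dens[label] = np.array(density, dtype=float)
        return replace(self, channel_densities=dens)


def _merge(base: dict, override: Mapping | None) -> dict:
    if not override:
        return {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    out = {}
    for k, v in base.items():
        if isinstance(v, dict):
            sub = override.get(k, {}) if isinstance(override, Mapping) else {}
            out[k] = _merge(v, sub)
        else:
            out[k] = override.get(k, v) if isinstance(override, Mapping) else v
    # allow extra keys only where they are meaningful (densities for new channels)
    extra = set(override) - set(base) if isinstance(override, Mapping) else set()
    for k in extra:
        out[k] = override[k]
    return out


def build_mossy_fiber(config: Mapping | None = None) -> CellModel:
    """Build the en-passant mossy-fiber chain from a parameter tree.

    Parameters
    ----------
    config : mapping, optional
        Partial override of :data:`DEFAULT_MODEL_CONFIG`.  With the defaults
        the cell has 22 sections and 1150 segments
        (10 soma + 11 x 100 axon + 10 x 4 bouton).

    Raises
    ------
    ModelConfigError
        Non-positive geometry or counts.
    UnknownChannelError
        A density map naming a channel other than ``na``/``k``.
    """
    cfg = _merge(DEFAULT_MODEL_CONFIG, config)
    geo = cfg["geometry"]
    pas = cfg["passive"]
    dens = cfg["densities_ms_cm2"]

    unknown = set(dens) - set(KNOWN_CHANNELS)
    if unknown:
        raise UnknownChannelError(
            f"unknown channel(s) in density map: {sorted(unknown)}; "
            f"known: {list(KNOWN_CHANNELS)}"
        )

    n_axon = int(geo["axon"]["count"])
    n_bouton = int(geo["bouton"]["count"])
    if n_axon < 1:
        raise ModelConfigError("need at least one axonal cylinder")
    if n_bouton not in (0, n_axon - 1):
        raise ModelConfigError(
            "en passant chain requires bouton count = axon count - 1 "
            f"(or 0); got {n_bouton} boutons, {n_axon} axons"
        )
    spu = float(geo["segments_per_um"])
    if spu <= 0:
        raise ModelConfigError("segments_per_um must be positive")

    passive_kwargs = dict(
        c_m_uf_cm2=float(pas["c_m_uf_cm2"]),
        r_m_ohm_cm2=float(pas["r_m_ohm_cm2"]),
        r_i_ohm_cm=float(pas["r_i_ohm_cm"]),
        e_leak_mv=float(pas["e_leak_mv"]),
    )

    def section(name: str, kind: str) -> SectionSpec:
        g = geo[kind]
        return SectionSpec(
            name=name,
            kind=kind,
            length_um=float(g["length_um"]),
            diameter_um=float(g["diameter_um"]),
            n_segments=default_n_segments(float(g["length_um"]), spu),
            channel_densities={ch: float(dens[ch][kind]) for ch in dens},
            **passive_kwargs,
        )

    sections = [section("soma", "soma")]
    for k in range(1, n_axon + 1):
        sections.append(section(f"axon_{k}", "axon"))
        if k <= n_bouton:
            sections.append(section(f"bouton_{k}", "bouton"))
    return CellModel.from_sections(sections)


def apply_depolarization_zone(
    model: CellModel, zone: Iterable[str], el_target_mv: float
) -> CellModel:
    """Return a copy of ``model`` with the leak reversal of every segment in
    the named landmarks set to ``el_target_mv``.

    Shifting the leak reversal locally is how depolarization by extracellular
    K+ accumulation is emulated: the affected membrane is pulled toward the
    target potential through its own leak conductance, while the actual
    steady-state V_m stays short of the target because the zone is coupled to
    non-depolarized neighbours.
    """
    if not np.isfinite(el_target_mv):
        raise ModelConfigError("el_target must be finite")
    el = np.array(model.e_leak, dtype=float)
    for name in zone:
        start, stop = model.landmark_range(name)
        el[start:stop] = el_target_mv
    return model.with_e_leak(el)


def site_index(model: CellModel, name: str, pos: float = 0.5) -> int:
    """Global segment index at normalized position ``pos`` in a landmark.

    ``pos = 0.5`` (default) addresses the centre segment, the convention for
    recording and injection sites.
    """
    if not (0.0 <= pos < 1.0 or pos == 1.0):
        raise ValueError("pos must lie in [0, 1]")
    start, stop = model.landmark_range(name)
    n = stop - start
    return start + min(int(pos * n), n - 1)
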