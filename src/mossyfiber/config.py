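"""YAML/JSON parameter trees for the model, protocols and fixtures.

The model configuration schema (all keys optional; defaults in
:data:`mossyfiber.morphology.DEFAULT_MODEL_CONFIG`)::

    geometry:
      soma:   {diameter_um: 10.0, length_um: 10.0}
      axon:   {diameter_um: 0.2, length_um: 100.0, count: 11}
      bouton: {diameter_um: 4.0, length_um: 4.0, count: 10}
      segments_per_um: 1.0
    passive:
      c_m_uf_cm2: 1.0          # specific membrane capacitance
      r_m_ohm_cm2: 10000.0     # specific membrane resistance
      r_i_ohm_cm: 110.0        # intracellular resistivity
      e_leak_mv: -80.0         # leak reversal = resting potential target
    densities_ms_cm2:
      na: {soma: 10.0, axon: 50.0, bouton: 50.0}
      k:  {soma: 36.0, axon: 36.0, bouton: 36.0}
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .morphology import DEFAULT_MODEL_CONFIG

__all__ = ["load_config", "save_config", "DEFAULT_MODEL_CONFIG"]


def load_config(path) -> dict:
    """Read a YAML or JSON parameter tree."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(tree: dict, path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(tree, indent=1, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(tree, sort_keys=False))
    return path
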