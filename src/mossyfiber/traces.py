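"""Recorded membrane-potential time series and their on-disk formats.

A :class:`TraceSet` holds V_m (mV) on a uniform time grid (ms) for one or
more named recording sites, plus provenance metadata (dt, the protocol that
produced it, stimulus end time).  Two interchangeable formats are supported:

* CSV — column 1 is time in ms, one column per site, header row = labels.
  Metadata travels in a sidecar ``<file>.meta.json`` when written by this
  module (plain CSVs from elsewhere load fine without it).
* HDF5 — one dataset per site plus a ``time`` dataset; metadata as root
  attributes (JSON-encoded where structured).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["TraceSet"]


@dataclass
class TraceSet:
    time_ms: np.ndarray
    data: dict  # site label -> ndarray, same length as time_ms
    dt_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, float)
        n = self.time_ms.size
        for site, v in self.data.items():
            v = np.asarray(v, float)
            if v.size != n:
                raise ValueError(
                    f"site {site!r}: length {v.size} != time grid {n}"
                )
            self.data[site] = v
        if n > 1:
            steps = np.diff(self.time_ms)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise ValueError("time grid must be uniform")

    @property
    def sites(self) -> list:
        return list(self.data)

    def __getitem__(self, site: str) -> np.ndarray:
        return self.data[site]

    @property
    def stimulus_end_ms(self):
        return self.meta.get("stimulus_end_ms")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.time_ms, **self.data})

    # ------------------------------------------------------------------ CSV

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        meta = dict(self.meta, dt_ms=self.dt_ms)
        Path(str(path) + ".meta.json").write_text(
            json.dumps(meta, indent=1, sort_keys=True)
        )
        return path

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        path = Path(path)
        df = pd.read_csv(path)
        tcol = df.columns[0]
        t = df[tcol].to_numpy(float)
        data = {c: df[c].to_numpy(float) for c in df.columns[1:]}
        meta_path = Path(str(path) + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        dt = float(meta.pop("dt_ms", t[1] - t[0] if t.size > 1 else 0.0))
        return cls(time_ms=t, data=data, dt_ms=dt, meta=meta)

    # ----------------------------------------------------------------- HDF5

    def to_hdf5(self, path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time_ms)
            grp = f.create_group("sites")
            for site, v in self.data.items():
                grp.create_dataset(site, data=v)
            f.attrs["dt_ms"] = self.dt_ms
            f.attrs["site_order"] = json.dumps(self.sites)
            f.attrs["meta"] = json.dumps(self.meta, sort_keys=True)
        return path

    @classmethod
    def from_hdf5(cls, path) -> "TraceSet":
        with h5py.File(path, "r") as f:
            t = f["time"][:]
            order = json.loads(f.attrs.get("site_order", "null")) or list(f["sites"])
            data = {site: f["sites"][site][:] for site in order}
            meta = json.loads(f.attrs.get("meta", "{}"))
            dt = float(f.attrs["dt_ms"])
        return cls(time_ms=t, data=data, dt_ms=dt, meta=meta)

    @classmethod
    def load(cls, path) -> "TraceSet":
        """Format-sniffing loader (by suffix: .csv vs .h5/.hdf5)."""
        path = Path(path)
        if path.suffix.lower() in (".h5", ".hdf5"):
            return cls.from_hdf5(path)
        return cls.from_csv(path)
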