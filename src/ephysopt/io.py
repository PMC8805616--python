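"""File I/O: HDF5 sweep container, CSV spike tables, JSON configuration.

HDF5 layout
-----------
One group per sweep, named ``sweep_000``, ``sweep_001``, ...  Each group has a
``samples`` dataset (float64) and attributes ``sampling_rate`` (Hz), ``unit``
(one of mV / pA / uV), ``t0`` (s) and ``label``.  The file root may carry a
``protocol`` attribute holding a JSON-encoded protocol description.

Spike times travel as RFC-4180 CSV with a header row and columns
``unit_id, trial, spike_time``; trial windows as ``trial, pre_start,
stim_start, stim_end``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import (FormatError, DataError, LightProtocol, StepProtocol,
                   TimeSeries)


def _protocol_to_dict(protocol) -> dict:
    d = dataclasses.asdict(protocol)
    d["__type__"] = type(protocol).__name__
    return d


def _protocol_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("__type__", None)
    if kind == "StepProtocol":
        return StepProtocol(**{k: tuple(v) if k == "amplitudes" else v
                               for k, v in d.items()})
    if kind == "LightProtocol":
        d["pulse_onsets"] = tuple(d["pulse_onsets"])
        return LightProtocol(**d)
    return None


def write_traces(path: str, traces: Sequence[TimeSeries], protocol=None):
    """Write sweeps (and optional protocol metadata) to the HDF5 container."""
    with h5py.File(path, "w") as f:
        if protocol is not None:
            f.attrs["protocol"] = json.dumps(_protocol_to_dict(protocol))
        for i, ts in enumerate(traces):
            g = f.create_group(f"sweep_{i:03d}")
            g.create_dataset("samples", data=ts.samples)
            g.attrs["sampling_rate"] = ts.sampling_rate
            g.attrs["unit"] = ts.unit
            g.attrs["t0"] = ts.t0
            g.attrs["label"] = ts.label
            for k, v in ts.meta.items():
                if isinstance(v, (bool, int, float, str)):
                    g.attrs[f"meta_{k}"] = v


def read_traces(path: str):
    """Read sweeps from the HDF5 container.

    Returns ``(traces, protocol)``; ``protocol`` is None when the file
    carries no protocol attribute.  Missing sampling-rate or unit attributes
    raise :class:`FormatError`; non-finite samples raise :class:`DataError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    traces = []
    with h5py.File(path, "r") as f:
        protocol = None
        if "protocol" in f.attrs:
            protocol = _protocol_from_dict(json.loads(f.attrs["protocol"]))
        for name in sorted(k for k in f.keys() if k.startswith("sweep_")):
            g = f[name]
            if "samples" not in g:
                raise FormatError(f"{name}: missing 'samples' dataset")
            for attr in ("sampling_rate", "unit"):
                if attr not in g.attrs:
                    raise FormatError(f"{name}: missing attribute {attr!r}")
            samples = np.asarray(g["samples"][()], dtype=np.float64)
            if not np.all(np.isfinite(samples)):
                raise DataError(f"{name}: non-finite samples")
            unit = g.attrs["unit"]
            if isinstance(unit, bytes):
                unit = unit.decode()
            label = g.attrs.get("label", "")
            if isinstance(label, bytes):
                label = label.decode()
            meta = {k[5:]: (bool(v) if isinstance(v, (bool, np.bool_)) else v)
                    for k, v in g.attrs.items() if k.startswith("meta_")}
            traces.append(TimeSeries(samples=samples,
                                     sampling_rate=float(g.attrs["sampling_rate"]),
                                     unit=str(unit), t0=float(g.attrs.get("t0", 0.0)),
                                     label=str(label), meta=meta))
    return traces, protocol


def write_spike_csv(path: str, rows: pd.DataFrame):
    """Write a spike-time table (unit_id, trial, spike_time) as CSV."""
    rows.to_csv(path, index=False)


def read_spike_csv(path: str) -> pd.DataFrame:
    """Read a spike-time CSV; validates required columns and sorted times."""
    df = pd.read_csv(path)
    for col in ("unit_id", "trial", "spike_time"):
        if col not in df.columns:
            raise FormatError(f"spike CSV missing column {col!r}")
    if not np.all(np.isfinite(df["spike_time"].to_numpy(dtype=float))):
        raise DataError("non-finite spike times")
    return df.sort_values(["unit_id", "trial", "spike_time"]).reset_index(drop=True)


def read_config(path: str) -> dict:
    with open(path) as f:
        cfg = json.load(f)
    if not isinstance(cfg, dict):
        raise FormatError("config JSON must be an object")
    return cfg


def write_config(path: str, cfg: dict):
    with open(path, "w") as f:
        json.dump(cfg, f, indent=2, sort_keys=True)
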