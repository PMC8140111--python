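"""File formats: columnar time series, interferogram stacks, result JSON.

Signal files are plain CSV with a ``time_s`` column and unit-suffixed
channel names (``pressure_Pa``, ``Lp_m``).  Interferogram stacks are
stored as a compressed NumPy archive next to a JSON manifest describing
the spectrometer and provenance; small stacks can also be exported as
plain text for fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_forward import InterferogramStack, SpectrometerSpec

__all__ = [
    "SignalTrace",
    "read_timeseries",
    "write_timeseries",
    "save_stack",
    "load_stack",
    "write_json",
]


@dataclass
class SignalTrace:
    """A uniformly sampled time series with units and provenance."""

    name: str
    time: np.ndarray
    values: np.ndarray
    unit: str = ""
    source: str = ""

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


def read_timeseries(path) -> dict[str, SignalTrace]:
    """Read a CSV of named channels sharing a ``time_s`` axis.

    The time grid must be strictly increasing and uniform to within 1% of
    the sampling interval.  Units are taken from the column-name suffix
    after the last underscore (``pressure_Pa`` -> unit ``Pa``).
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    if len(df.columns) < 2:
        raise ValueError(f"{path}: no data channels besides time")
    time = df["time_s"].to_numpy(float)
    dt = np.diff(time)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError(f"{path}: time axis must be strictly increasing")
    step = np.median(dt)
    if np.max(np.abs(dt - step)) > 0.01 * step:
        raise ValueError(f"{path}: time grid jitter exceeds 1% of the interval")
    traces = {}
    for col in df.columns:
        if col == "time_s":
            continue
        unit = col.rsplit("_", 1)[1] if "_" in col else ""
        traces[col] = SignalTrace(name=col, time=time,
                                  values=df[col].to_numpy(float), unit=unit,
                                  source=str(path))
    return traces


def write_timeseries(path, time: np.ndarray, channels: dict[str, np.ndarray]) -> None:
    """Write channels to CSV; keys should carry unit suffixes."""
    df = pd.DataFrame({"time_s": np.asarray(time)})
    for name, values in channels.items():
        df[name] = np.asarray(values)
    df.to_csv(path, index=False)


def save_stack(path, stack: InterferogramStack) -> None:
    """Store a stack as ``<path>.npz`` plus a ``<path>.json`` manifest."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"),
                        time=stack.time, frames=stack.frames)
    manifest = {"spectrometer": dataclasses.asdict(stack.spec),
                "n_frames": int(stack.frames.shape[0]),
                "n_pixels": int(stack.frames.shape[1]),
                "provenance": stack.provenance}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_stack(path) -> InterferogramStack:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    spec = SpectrometerSpec(**manifest["spectrometer"])
    with np.load(path.with_suffix(".npz")) as data:
        stack = InterferogramStack(time=data["time"], frames=data["frames"],
                                   spec=spec,
                                   provenance=manifest.get("provenance", {}))
    return stack


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
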