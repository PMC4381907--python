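"""Recording container and its CSV dialect.

A recording is a time-aligned set of command voltage, current, and raw
fluorescence samples plus metadata.  On disk it is a plain CSV with
metadata header lines prefixed ``#`` (``# key: json-value``), then the
column header ``time_ms,voltage_mV,current,fluorescence``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Any

import numpy as np
import pandas as pd


@dataclass
class Recording:
    """One synthetic (or imported) voltage-clamp-fluorometry sweep."""

    times_ms: np.ndarray
    voltage_mv: np.ndarray
    current: np.ndarray
    fluorescence: np.ndarray
    meta: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = [self.times_ms, self.voltage_mv, self.current, self.fluorescence]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("all series must have equal length")
        t = np.asarray(self.times_ms, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        rate = self.meta.get("sample_rate_hz")
        if rate is not None and len(t) > 1:
            dt = np.diff(t)
            if abs(np.median(dt) - 1000.0 / rate) > 1e-6 * max(1.0, 1000.0 / rate):
                raise ValueError("sample rate metadata inconsistent with time grid")

    @property
    def sample_rate_hz(self) -> float:
        if "sample_rate_hz" in self.meta:
            return float(self.meta["sample_rate_hz"])
        return 1000.0 / float(np.median(np.diff(self.times_ms)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "voltage_mV": self.voltage_mv,
                "current": self.current,
                "fluorescence": self.fluorescence,
            }
        )

    def slice_time(self, t0_ms: float, t1_ms: float) -> "Recording":
        m = (self.times_ms >= t0_ms - 1e-9) & (self.times_ms <= t1_ms + 1e-9)
        return Recording(
            self.times_ms[m], self.voltage_mv[m], self.current[m], self.fluorescence[m],
            dict(self.meta),
        )


def write_recording_csv(rec: Recording, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(rec.meta):
            fh.write(f"# {key}: {json.dumps(rec.meta[key])}\n")
        rec.to_frame().to_csv(fh, index=False, lineterminator="\n")


def read_recording_csv(path) -> Recording:
    meta: Dict[str, Any] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = json.loads(val.strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return Recording(
        times_ms=df["time_ms"].to_numpy(),
        voltage_mv=df["voltage_mV"].to_numpy(),
        current=df["current"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
        meta=meta,
    )
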