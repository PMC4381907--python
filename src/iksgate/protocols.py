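"""Piecewise-constant voltage-clamp protocols and named presets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import yaml

HOLDING_MV = -80.0


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered piecewise-constant voltage segments.

    segments: list of (duration_ms, voltage_mv); sample_interval_ms sets the
    output grid (1 ms = 1 kHz by default) and must divide every segment
    boundary; holding_voltage_mv is the pre-protocol potential used when the
    initial occupancy is "equilibrium at holding".
    """

    segments: Tuple[Tuple[float, float], ...]
    sample_interval_ms: float = 1.0
    holding_voltage_mv: float = HOLDING_MV

    def __init__(self, segments, sample_interval_ms=1.0, holding_voltage_mv=HOLDING_MV):
        object.__setattr__(self, "segments", tuple((float(d), float(v)) for d, v in segments))
        object.__setattr__(self, "sample_interval_ms", float(sample_interval_ms))
        object.__setattr__(self, "holding_voltage_mv", float(holding_voltage_mv))
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.sample_interval_ms <= 0:
            raise ValueError("sample interval must be positive")
        t = 0.0
        for d, v in self.segments:
            if d <= 0:
                raise ValueError("segment durations must be positive")
            t += d
            ratio = t / self.sample_interval_ms
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"sample interval {self.sample_interval_ms} ms does not divide "
                    f"segment boundary at {t} ms"
                )

    @property
    def total_duration_ms(self) -> float:
        return sum(d for d, _ in self.segments)

    def times_ms(self) -> np.ndarray:
        n = int(round(self.total_duration_ms / self.sample_interval_ms))
        return np.arange(n + 1) * self.sample_interval_ms

    def voltage_at(self, times_ms: Sequence[float]) -> np.ndarray:
        """Command voltage on a time grid; a boundary sample takes the
        voltage of the segment that starts there (the new command is already
        applied when the sample is taken)."""
        times = np.asarray(times_ms, dtype=float)
        edges = np.cumsum([d for d, _ in self.segments])
        volts = np.array([v for _, v in self.segments])
        idx = np.searchsorted(edges, times, side="right")
        idx = np.minimum(idx, len(volts) - 1)
        return volts[idx]

    def with_prepulse(self, duration_ms: float) -> "VoltageProtocol":
        """Prepend a holding-potential segment (e.g. a 2 s baseline window)."""
        return VoltageProtocol(
            ((duration_ms, self.holding_voltage_mv),) + self.segments,
            self.sample_interval_ms,
            self.holding_voltage_mv,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "segments": [list(s) for s in self.segments],
                    "sample_interval_ms": self.sample_interval_ms,
                    "holding_voltage_mv": self.holding_voltage_mv,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "VoltageProtocol":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            [tuple(s) for s in d["segments"]],
            d.get("sample_interval_ms", 1.0),
            d.get("holding_voltage_mv", HOLDING_MV),
        )


def step_protocol(
    test_mv: float,
    pulse_ms: float = 4000.0,
    tail_mv: float = 60.0,
    tail_ms: float = 1000.0,
    sample_interval_ms: float = 1.0,
) -> VoltageProtocol:
    """Test pulse followed by a tail step, from a -80 mV holding potential."""
    return VoltageProtocol(
        [(pulse_ms, test_mv), (tail_ms, tail_mv)],
        sample_interval_ms=sample_interval_ms,
    )


def preset_protocol(name: str, test_mv: float | None = None, **kwargs) -> VoltageProtocol:
    """Named protocol presets.

    * ``vcf_family``:     4 s test pulse, 1 s tail at +60 mV (VCF / IV family)
    * ``permeability``:   5 s at +60 mV, 3 s tail at -60 mV (Rb+/K+ tails)
    * ``xe991``:          2 s test pulse, 1 s tail at -40 mV (inhibition)
    """
    presets = {
        "vcf_family": dict(pulse_ms=4000.0, tail_mv=60.0, tail_ms=1000.0),
        "permeability": dict(pulse_ms=5000.0, tail_mv=-60.0, tail_ms=3000.0),
        "xe991": dict(pulse_ms=2000.0, tail_mv=-40.0, tail_ms=1000.0),
    }
    default_test = {"vcf_family": 0.0, "permeability": 60.0, "xe991": 60.0}
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    if test_mv is None:
        test_mv = default_test[name]
    cfg = {**presets[name], **kwargs}
    return step_protocol(test_mv, **cfg)
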