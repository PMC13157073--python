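"""Sampled current traces and their on-disk format.

A trace is a uniformly sampled current (pA) plus acquisition metadata:
holding voltage, sampling rate, the append-only filter history, and the
pressure protocol.  On disk a trace is a two-column tab-separated file
(time_ms, current_pA) with a JSON sidecar carrying the metadata, so records
survive as plain text and round-trip exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RecordingTrace", "write_trace", "read_trace"]


@dataclass
class RecordingTrace:
    current_pA: np.ndarray
    sampling_rate_hz: float
    voltage_mV: float = -60.0
    pressure_segments: list[tuple[float, float, float]] = field(default_factory=list)
    filters: list[dict] = field(default_factory=list)  # append-only history
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        if self.current_pA.ndim != 1 or self.current_pA.size == 0:
            raise ValueError("trace must be a non-empty 1-D current array")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be > 0")

    def __len__(self) -> int:
        return self.current_pA.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def duration_ms(self) -> float:
        return len(self) * self.dt_ms

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt_ms

    @property
    def burn_in_ms(self) -> float:
        """Settling interval of the narrowest filter applied so far (5/fc)."""
        cutoffs = [f["cutoff_hz"] for f in self.filters]
        if not cutoffs:
            return 0.0
        return 5.0 / min(cutoffs) * 1000.0

    def replace(self, current_pA: np.ndarray, extra_filter: dict | None = None) -> "RecordingTrace":
        filters = list(self.filters) + ([extra_filter] if extra_filter else [])
        return RecordingTrace(
            current_pA=current_pA,
            sampling_rate_hz=self.sampling_rate_hz,
            voltage_mV=self.voltage_mV,
            pressure_segments=list(self.pressure_segments),
            filters=filters,
            meta=dict(self.meta),
        )

    def pressure_onset_ms(self) -> float | None:
        """Start of the first nonzero-pressure segment, if any."""
        for start, _end, p in self.pressure_segments:
            if p != 0:
                return float(start)
        return None


def write_trace(trace: RecordingTrace, path: str | Path) -> None:
    path = Path(path)
    data = np.column_stack([trace.time_ms, trace.current_pA])
    np.savetxt(path, data, fmt="%.4f\t%.6f", header="time_ms\tcurrent_pA", comments="")
    sidecar = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "voltage_mv": trace.voltage_mV,
        "filters": trace.filters,
        "pressure_segments": [list(s) for s in trace.pressure_segments],
        **trace.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path: str | Path) -> RecordingTrace:
    path = Path(path)
    data = np.loadtxt(path, skiprows=1)
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    meta = {
        k: v
        for k, v in side.items()
        if k not in ("sampling_rate_hz", "voltage_mv", "filters", "pressure_segments")
    }
    return RecordingTrace(
        current_pA=data[:, 1],
        sampling_rate_hz=float(side["sampling_rate_hz"]),
        voltage_mV=float(side["voltage_mv"]),
        pressure_segments=[tuple(s) for s in side.get("pressure_segments", [])],
        filters=side.get("filters", []),
        meta=meta,
    )
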