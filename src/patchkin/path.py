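"""Idealized dwell sequences.

An :class:`IdealizedPath` is the common currency of the package: the gating
simulator emits one as ground truth, and the Viterbi idealizer reconstructs
one from a noisy trace.  It is an ordered, contiguous tiling of the analyzed
interval by dwells (state label, start, duration, current level), with the
first and last dwell flagged as censored because their true onset/offset lies
outside the record.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IdealizedPath"]


@dataclass
class IdealizedPath:
    states: np.ndarray  # dwell state labels (str)
    start_ms: np.ndarray
    duration_ms: np.ndarray
    level_pA: np.ndarray
    censored_first: bool = True
    censored_last: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        self.start_ms = np.asarray(self.start_ms, dtype=float)
        self.duration_ms = np.asarray(self.duration_ms, dtype=float)
        self.level_pA = np.asarray(self.level_pA, dtype=float)
        n = len(self.states)
        if not (len(self.start_ms) == len(self.duration_ms) == len(self.level_pA) == n):
            raise ValueError("dwell arrays must have equal length")
        if n == 0:
            raise ValueError("a path needs at least one dwell")
        if np.any(self.duration_ms <= 0):
            raise ValueError("dwell durations must be > 0")
        ends = self.start_ms + self.duration_ms
        if not np.allclose(ends[:-1], self.start_ms[1:], atol=1e-6):
            raise ValueError("dwells must be contiguous and non-overlapping")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def total_ms(self) -> float:
        return float(self.start_ms[-1] + self.duration_ms[-1] - self.start_ms[0])

    def censored_mask(self) -> np.ndarray:
        m = np.zeros(len(self), dtype=bool)
        if self.censored_first:
            m[0] = True
        if self.censored_last:
            m[-1] = True
        return m

    def dwells(self, state: str, censored: bool = False) -> np.ndarray:
        """Durations of dwells in one state (uncensored only by default)."""
        sel = self.states == state
        if not censored:
            sel &= ~self.censored_mask()
        return self.duration_ms[sel]

    def levels_at(self, t_ms: np.ndarray) -> np.ndarray:
        """Current level at sample times (piecewise constant, right-open)."""
        idx = np.searchsorted(self.start_ms, t_ms, side="right") - 1
        idx = np.clip(idx, 0, len(self) - 1)
        return self.level_pA[idx]

    def states_at(self, t_ms: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.start_ms, t_ms, side="right") - 1
        idx = np.clip(idx, 0, len(self) - 1)
        return self.states[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.states,
                "start_ms": self.start_ms,
                "duration_ms": self.duration_ms,
                "level_pA": self.level_pA,
                "censored": self.censored_mask(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **meta) -> "IdealizedPath":
        return cls(
            states=df["state"].to_numpy(),
            start_ms=df["start_ms"].to_numpy(),
            duration_ms=df["duration_ms"].to_numpy(),
            level_pA=df["level_pA"].to_numpy(),
            meta=meta,
        )

    @classmethod
    def from_samples(
        cls,
        state_labels: np.ndarray,
        levels: np.ndarray,
        dt_ms: float,
        t0_ms: float = 0.0,
        **meta,
    ) -> "IdealizedPath":
        """Build a path by run-length encoding a per-sample state sequence."""
        state_labels = np.asarray(state_labels)
        change = np.flatnonzero(state_labels[1:] != state_labels[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(state_labels)]))
        return cls(
            states=state_labels[starts],
            start_ms=t0_ms + starts * dt_ms,
            duration_ms=(ends - starts) * dt_ms,
            level_pA=np.asarray(levels, dtype=float)[starts],
            meta=meta,
        )
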