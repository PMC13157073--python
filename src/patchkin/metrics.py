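"""Histogram-derived single-channel quantities.

Open probability follows the area convention Po = Ao / (Ac + Ao), where Ac is
the shut-peak area of the all-point histogram and Ao the summed area of the
conducting peaks (sub-conductance included by default — any conducting level
counts as open for Po).  Multi-channel patches are reduced to a per-channel Po
by dividing the time-weighted mean open-channel count (NPo) by the channel
count N.  Conductances are reported as magnitudes in pS.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .idealize import AmplitudeModel

__all__ = [
    "StateMetrics",
    "po_from_areas",
    "adjust_po_multichannel",
    "unitary_current",
    "chord_conductance",
    "slope_conductance",
    "fold_change",
]

ELEMENTARY_CHARGE_C = 1.602176634e-19


@dataclass
class StateMetrics:
    """Per-recording summary of gating and permeation metrics."""

    po: float
    occupancy: dict[str, float]
    mean_lifetime_ms: dict[str, float | None]
    unitary_current_pA: dict[str, float]
    conductance_pS: float
    e_rate_per_s: dict[str, float]
    n_channels: int
    pressure_mmHg: float = 0.0
    yoda1: bool = False
    voltage_mV: float = -60.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.po <= 1.0:
            raise ValueError(f"Po = {self.po} outside [0, 1]")
        tot = sum(self.occupancy.values())
        if self.occupancy and not np.isclose(tot, 1.0, atol=1e-9):
            raise ValueError(f"occupancies sum to {tot}, not 1")
        if any(v < 0 for v in self.e_rate_per_s.values()):
            raise ValueError("elementary charge rates must be >= 0")

    def to_row(self) -> dict:
        row = {
            "po": self.po,
            "conductance_pS": self.conductance_pS,
            "n_channels": self.n_channels,
            "pressure_mmHg": self.pressure_mmHg,
            "yoda1": self.yoda1,
            "voltage_mV": self.voltage_mV,
        }
        for k, v in self.occupancy.items():
            row[f"occ_{k}"] = v
        for k, v in self.mean_lifetime_ms.items():
            row[f"lifetime_{k}_ms"] = v
        for k, v in self.unitary_current_pA.items():
            row[f"i_{k}_pA"] = v
        for k, v in self.e_rate_per_s.items():
            row[f"e_rate_{k}"] = v
        return row


def po_from_areas(model: AmplitudeModel, include_sub: bool = True) -> float:
    """Po = Ao / (Ac + Ao) from the fitted peak areas.

    ``include_sub=False`` counts only the full-open component (the largest
    |mean| conducting peak) toward Ao.
    """
    ac = model.area_shut
    cond = model.conducting
    if include_sub or len(cond) <= 1:
        ao = sum(c.area for c in cond)
    else:
        ao = cond[-1].area
    if ac + ao <= 0:
        raise ValueError("Ac + Ao = 0: no fitted area to form Po")
    po = ao / (ac + ao)
    return float(min(max(po, 0.0), 1.0))


def adjust_po_multichannel(level_time_fractions: dict[int, float], n_channels: int) -> float:
    """Single-channel Po from summed-level time fractions: (sum_k k*f_k) / N.

    ``level_time_fractions`` maps the number of simultaneously conducting
    channels k to the fraction of time spent at that summed level.  The
    time-weighted mean level is NPo; dividing by the channel count N gives the
    per-channel Po.  Reduces to the unadjusted value at N = 1.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    fracs = {int(k): float(f) for k, f in level_time_fractions.items()}
    total = sum(fracs.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"level time fractions sum to {total}, not 1")
    if max(fracs) > n_channels:
        raise ValueError(
            f"observed summed level {max(fracs)} exceeds channel count {n_channels}"
        )
    npo = sum(k * f for k, f in fracs.items())
    return float(npo / n_channels)


def unitary_current(model: AmplitudeModel) -> dict[str, float]:
    """Shut-referenced current of each conducting level.

    For a single-channel model the components ordered by |mean| are
    shut (, sub), open; currents are component means minus the shut mean.
    """
    cond = model.conducting
    if not cond:
        raise ValueError("no conducting component in the amplitude model")
    shut_mean = model.shut.mean_pA
    out = {"open": cond[-1].mean_pA - shut_mean}
    if len(cond) >= 2:
        out["sub"] = cond[0].mean_pA - shut_mean
    return out


def chord_conductance(current_pA: float, voltage_mV: float) -> float:
    """Chord conductance |i / V| in pS (1 pA / 1 mV = 1000 pS)."""
    if voltage_mV == 0:
        raise ValueError("chord conductance undefined at 0 mV")
    return abs(1000.0 * current_pA / voltage_mV)


def slope_conductance(iv_points: list[tuple[float, float]]) -> tuple[float, float]:
    """Slope conductance from an I-V relationship.

    Parameters
    ----------
    iv_points : list of (voltage_mV, current_pA)

    Returns
    -------
    (conductance_pS, r_squared)
    """
    if len(iv_points) < 2:
        raise ValueError("need at least two I-V points")
    v = np.array([p[0] for p in iv_points], dtype=float)
    i = np.array([p[1] for p in iv_points], dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("need at least two distinct voltages")
    res = sps.linregress(v, i)
    return abs(1000.0 * res.slope), float(res.rvalue**2)


def fold_change(po_after: float, po_before: float) -> float:
    """Ratio of open probabilities (after / before)."""
    if po_before <= 0:
        raise ValueError("undefined fold change: reference Po is zero")
    return float(po_after / po_before)
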