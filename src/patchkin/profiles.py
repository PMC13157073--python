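"""Variant gating profiles.

A :class:`VariantProfile` bundles everything the simulator needs for one
channel variant: unitary currents, per-condition gating schemes (rest,
pressure, agonist, fast pressure-step), and the inactivation time constant.
Profiles ship as YAML fixtures calibrated so the stationary open probability,
per-state occupancy and mean lifetimes equal the published per-variant group
values; rates are solved from those targets at load time by
:func:`patchkin.scheme.calibrate_rates_to_targets`.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from .scheme import (
    KineticScheme,
    calibrate_rates_to_targets,
    scale_opening_rates,
    stationary_distribution,
)

__all__ = ["VariantProfile", "load_profile", "list_profiles", "open_probability"]

_RATE_KEYS = {
    "shut->open": ("shut", "open"),
    "open->shut": ("open", "shut"),
    "shut->sub": ("shut", "sub"),
    "sub->shut": ("sub", "shut"),
    "sub->open": ("sub", "open"),
    "open->sub": ("open", "sub"),
}


def open_probability(scheme: KineticScheme) -> float:
    """Stationary Po: total occupancy of conducting (sub + open) states."""
    pi = stationary_distribution(scheme)
    return float(
        sum(p for p, s in zip(pi, scheme.states) if s.label in ("sub", "open"))
    )


@dataclass
class ConditionTargets:
    pressure_mmHg: float
    occupancy: dict[str, float]
    mean_lifetime_ms: dict[str, float]


@dataclass
class VariantProfile:
    """Gating model of one channel variant across stimulus conditions."""

    name: str
    label: str
    open_current_pA: float
    sub_current_pA: float
    reference_voltage_mV: float
    tau_inact_ms: float
    recovery_rate_per_s: float
    yoda1_po_fold: float | None
    conditions: dict[str, ConditionTargets]
    step_rates_per_s: dict[str, float]
    _schemes: dict[str, KineticScheme] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.tau_inact_ms <= 0:
            raise ValueError("tau_inact_ms must be > 0")
        if abs(self.sub_current_pA) >= abs(self.open_current_pA):
            raise ValueError("|sub current| must be < |open current|")

    # -- scheme construction -------------------------------------------------
    @property
    def state_currents(self) -> dict[str, float]:
        return {"shut": 0.0, "sub": self.sub_current_pA, "open": self.open_current_pA}

    def scheme(self, condition: str) -> KineticScheme:
        """Gating scheme for a named condition.

        Conditions: ``rest``, ``pressure`` (the calibrated steady state at the
        reference pressure), ``yoda1`` (agonist at the reference pressure) and
        ``step`` (saturating fast-activation scheme for pressure-step peaks).
        """
        if condition in self._schemes:
            return self._schemes[condition]
        if condition in self.conditions:
            tgt = self.conditions[condition]
            sch = calibrate_rates_to_targets(
                tgt.occupancy, tgt.mean_lifetime_ms, self.state_currents
            )
        elif condition == "step":
            sch = self._step_scheme()
        elif condition == "yoda1":
            sch = self._yoda1_scheme()
        else:
            raise KeyError(f"unknown condition {condition!r} for profile {self.name}")
        self._schemes[condition] = sch
        return sch

    def _step_scheme(self) -> KineticScheme:
        base = self.scheme("pressure")
        Q = np.zeros_like(base.Q)
        for key, (a, b) in _RATE_KEYS.items():
            if key in self.step_rates_per_s:
                Q[base.index(a), base.index(b)] = self.step_rates_per_s[key]
        return KineticScheme(base.states, Q)

    def _yoda1_scheme(self) -> KineticScheme:
        """Agonist condition: opening rates scaled so that stationary Po rises
        by the profile's calibrated Yoda1 fold at the reference pressure."""
        if self.yoda1_po_fold is None:
            raise ValueError(f"profile {self.name} has no Yoda1 calibration")
        base = self.scheme("pressure")
        po0 = open_probability(base)
        target = self.yoda1_po_fold * po0
        if not target < 1.0:
            raise ValueError("Yoda1 target Po must stay below 1")

        def gap(log_m: float) -> float:
            return open_probability(scale_opening_rates(base, float(np.exp(log_m)))) - target

        log_m = brentq(gap, np.log(1e-3), np.log(1e4), xtol=1e-12)
        return scale_opening_rates(base, float(np.exp(log_m)))

    def scheme_for_pressure(self, pressure_mmHg: float, yoda1: bool = False) -> KineticScheme:
        """Scheme at an arbitrary pressure.

        The two calibrated anchors (rest and the reference pressure) are used
        directly; other pressures interpolate each transition rate
        geometrically in |pressure|, the exponential rate-scaling model of the
        -10..-50 mmHg sweep.
        """
        ref = self.conditions["pressure"].pressure_mmHg
        if yoda1:
            if pressure_mmHg != ref:
                raise ValueError("Yoda1 condition is calibrated at the reference pressure")
            return self.scheme("yoda1")
        if pressure_mmHg == 0:
            return self.scheme("rest")
        if pressure_mmHg == ref:
            return self.scheme("pressure")
        w = abs(pressure_mmHg) / abs(ref)
        q0, q1 = self.scheme("rest").Q, self.scheme("pressure").Q
        Q = np.zeros_like(q0)
        both = (q0 > 0) & (q1 > 0)
        Q[both] = q0[both] ** (1 - w) * q1[both] ** w
        either = ((q0 > 0) | (q1 > 0)) & ~both
        Q[either] = (1 - w) * q0[either] + w * q1[either]  # linear fallback
        Q[Q < 0] = 0.0
        np.fill_diagonal(Q, 0.0)
        return KineticScheme(self.scheme("rest").states, Q)

    def unitary_current_at(self, voltage_mV: float) -> float:
        """Open-state current at a holding voltage (linear I-V through 0)."""
        return self.open_current_pA * voltage_mV / self.reference_voltage_mV


def _fixture_dir() -> Path:
    return Path(str(importlib.resources.files("patchkin") / "fixtures"))


def list_profiles() -> list[str]:
    return sorted(yaml.safe_load(p.read_text())["name"] for p in _fixture_dir().glob("*.yaml"))


def load_profile(name: str) -> VariantProfile:
    """Load a packaged variant profile (e.g. ``WT``, ``R537C``) or a YAML path."""
    path = Path(name)
    if not path.is_file():
        path = _fixture_dir() / f"{name.lower()}.yaml"
        if not path.is_file():
            raise FileNotFoundError(
                f"no profile fixture for {name!r}; available: {list_profiles()}"
            )
    raw = yaml.safe_load(path.read_text())
    conditions = {
        key: ConditionTargets(
            pressure_mmHg=float(val["pressure_mmHg"]),
            occupancy={k: float(v) for k, v in val["occupancy"].items()},
            mean_lifetime_ms={k: float(v) for k, v in val["mean_lifetime_ms"].items()},
        )
        for key, val in raw["conditions"].items()
    }
    return VariantProfile(
        name=raw["name"],
        label=raw.get("label", raw["name"]),
        open_current_pA=float(raw["open_current_pA"]),
        sub_current_pA=float(raw["sub_current_pA"]),
        reference_voltage_mV=float(raw["reference_voltage_mV"]),
        tau_inact_ms=float(raw["tau_inact_ms"]),
        recovery_rate_per_s=float(raw["recovery_rate_per_s"]),
        yoda1_po_fold=None if raw.get("yoda1_po_fold") is None else float(raw["yoda1_po_fold"]),
        conditions=conditions,
        step_rates_per_s={k: float(v) for k, v in raw["step_rates_per_s"].items()},
    )
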