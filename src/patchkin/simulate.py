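"""Stochastic simulation of cell-attached single-channel recordings.

The generative model is a continuous-time Markov chain over shut /
sub-conductance / open (and optionally inactivated) states, sampled with exact
event times (Gillespie) within each pressure segment; rates are piecewise
constant per segment and the state carries over segment boundaries.  Rendering
converts per-channel paths into a sampled current by summing unitary currents,
adding white Gaussian noise and applying the acquisition low-pass filter —
emulating a 10 kHz / 2 kHz patch-clamp acquisition chain.

Inactivation, when enabled, is entered from the open state at rate
1/tau_inact while pressure is applied; recovery back to shut happens only at
rest.  During a sustained step the inactivated state is therefore absorbing
and the ensemble-averaged current decays mono-exponentially.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .path import IdealizedPath
from .profiles import VariantProfile
from .scheme import GatingState, KineticScheme, stationary_distribution
from .trace import RecordingTrace

__all__ = [
    "StimulusProtocol",
    "SimConfig",
    "simulate_path",
    "render_trace",
    "make_cohort",
    "simulate_recording",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Holding voltage plus a contiguous sequence of pressure segments."""

    holding_voltage_mV: float = -60.0
    pressure_segments: tuple[tuple[float, float, float], ...] = ((0.0, 30_000.0, 0.0),)
    yoda1: bool = False

    def __post_init__(self) -> None:
        segs = tuple(tuple(map(float, s)) for s in self.pressure_segments)
        object.__setattr__(self, "pressure_segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one pressure segment")
        t = 0.0
        for start, end, _p in segs:
            if not np.isclose(start, t):
                raise ValueError("pressure segments must be contiguous from 0")
            if end <= start:
                raise ValueError("segment end must exceed its start")
            t = end
        object.__setattr__(self, "duration_ms", t)

    duration_ms: float = field(init=False, default=0.0)

    @classmethod
    def constant(
        cls, pressure_mmHg: float, duration_ms: float, voltage_mV: float = -60.0, yoda1: bool = False
    ) -> "StimulusProtocol":
        return cls(voltage_mV, ((0.0, duration_ms, pressure_mmHg),), yoda1)

    @classmethod
    def step(
        cls,
        pre_ms: float,
        step_ms: float,
        pressure_mmHg: float = -30.0,
        post_ms: float = 0.0,
        voltage_mV: float = -60.0,
    ) -> "StimulusProtocol":
        segs = [(0.0, pre_ms, 0.0), (pre_ms, pre_ms + step_ms, pressure_mmHg)]
        if post_ms > 0:
            segs.append((pre_ms + step_ms, pre_ms + step_ms + post_ms, 0.0))
        return cls(voltage_mV, tuple(segs))


@dataclass(frozen=True)
class SimConfig:
    """Acquisition settings for the rendered recording."""

    sampling_rate_hz: float = 10_000.0
    acq_filter_hz: float = 2_000.0
    noise_sd_pA: float = 0.15
    n_channels: int = 1
    duration_ms: float = 30_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 2 * self.acq_filter_hz:
            raise ValueError("sampling rate must exceed twice the acquisition cutoff")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.noise_sd_pA < 0 or self.duration_ms <= 0:
            raise ValueError("noise_sd must be >= 0 and duration > 0")


def _segment_scheme(
    profile: VariantProfile, pressure: float, yoda1: bool, inactivation: bool
) -> KineticScheme:
    if inactivation and pressure != 0:
        base = profile.scheme("step")
    else:
        base = profile.scheme_for_pressure(pressure, yoda1=yoda1 and pressure != 0)
    if not inactivation:
        return base
    # append the inactivated state with the pressure-gated transitions
    n = len(base.states)
    Q = np.zeros((n + 1, n + 1))
    Q[:n, :n] = base.Q
    np.fill_diagonal(Q, 0.0)
    states = base.states + (GatingState("inactivated", 0.0),)
    if pressure != 0:
        Q[base.index("open"), n] = 1000.0 / profile.tau_inact_ms
    else:
        Q[n, base.index("shut")] = profile.recovery_rate_per_s
    return KineticScheme(states, Q)


def simulate_path(
    profile: VariantProfile,
    protocol: StimulusProtocol,
    duration_ms: float | None = None,
    seed: int | np.random.Generator = 0,
    inactivation: bool = False,
) -> IdealizedPath:
    """Exact-event-time (Gillespie) simulation of one channel's gating path.

    The initial state is drawn from the stationary law of the first segment's
    scheme; each pressure segment uses its own rate matrix and the state is
    carried over boundaries.  The returned dwells tile [0, duration_ms].
    """
    if duration_ms is None:
        duration_ms = protocol.duration_ms
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    currents = {**profile.state_currents, "inactivated": 0.0}

    # dwell records under construction: (label, start)
    events: list[tuple[str, float]] = []
    state: str | None = None
    t = 0.0
    for start, end, pressure in protocol.pressure_segments:
        if start >= duration_ms:
            break
        end = min(end, duration_ms)
        sch = _segment_scheme(profile, pressure, protocol.yoda1, inactivation)
        if state is None:
            try:
                pi = stationary_distribution(sch)
            except ValueError:  # frozen (all-zero) scheme: start shut
                pi = np.zeros(len(sch.states))
                pi[sch.index("shut")] = 1.0
            state = sch.labels[rng.choice(len(pi), p=pi)]
            events.append((state, 0.0))
        labels = sch.labels
        Qms = sch.Q / 1000.0  # rates per ms
        while t < end:
            i = labels.index(state)
            rate = -Qms[i, i]
            if rate <= 0:  # absorbing in this segment
                t = end
                break
            wait = rng.exponential(1.0 / rate)
            if t + wait >= end:
                t = end
                break
            t += wait
            probs = Qms[i].copy()
            probs[i] = 0.0
            probs /= probs.sum()
            state = labels[rng.choice(len(labels), p=probs)]
            events.append((state, t))
        t = end
    # collapse consecutive identical states (can occur across boundaries)
    states, starts = [], []
    for lab, s in events:
        if states and states[-1] == lab:
            continue
        states.append(lab)
        starts.append(s)
    starts_arr = np.array(starts)
    durs = np.diff(np.append(starts_arr, duration_ms))
    return IdealizedPath(
        states=np.array(states, dtype=object),
        start_ms=starts_arr,
        duration_ms=durs,
        level_pA=np.array([currents[s] for s in states]),
        meta={"profile": profile.name, "protocol": protocol, "inactivation": inactivation},
    )


def render_trace(
    paths: list[IdealizedPath],
    profile: VariantProfile,
    config: SimConfig,
    protocol: StimulusProtocol | None = None,
) -> RecordingTrace:
    """Render per-channel gating paths into a sampled, noisy, filtered trace.

    The per-sample current is the sum over channels of the dwelling state's
    unitary current, plus zero-mean white Gaussian noise of ``noise_sd_pA``,
    passed through the acquisition low-pass (causal 4th-order Butterworth at
    ``acq_filter_hz``, as an anti-alias/acquisition-bandwidth stand-in).
    """
    if not paths:
        raise ValueError("at least one channel path is required")
    durations = {round(p.total_ms, 6) for p in paths}
    if len(durations) > 1:
        raise ValueError(f"channel paths have mismatched durations: {durations}")
    if protocol is None:
        protocol = paths[0].meta.get("protocol")
    dt_ms = 1000.0 / config.sampling_rate_hz
    n = int(round(min(config.duration_ms, paths[0].total_ms) / dt_ms))
    t_ms = np.arange(n) * dt_ms
    ideal = np.zeros(n)
    for p in paths:
        ideal += p.levels_at(t_ms)
    rng = np.random.default_rng([int(config.seed), 0x6E01])
    raw = ideal + rng.normal(0.0, config.noise_sd_pA, size=n)
    sos = signal.butter(4, config.acq_filter_hz, fs=config.sampling_rate_hz, output="sos")
    filtered = signal.sosfilt(sos, raw)
    return RecordingTrace(
        current_pA=filtered,
        sampling_rate_hz=config.sampling_rate_hz,
        voltage_mV=protocol.holding_voltage_mV if protocol else -60.0,
        pressure_segments=[tuple(s) for s in protocol.pressure_segments] if protocol else [],
        filters=[{"type": "butterworth", "cutoff_hz": config.acq_filter_hz, "order": 4,
                  "zero_phase": False, "stage": "acquisition"}],
        meta={
            "profile_name": profile.name,
            "n_channels_true": config.n_channels,
            "seed": int(config.seed),
            "noise_sd_pA": config.noise_sd_pA,
            "yoda1": bool(protocol.yoda1) if protocol else False,
        },
    )


def simulate_recording(
    profile: VariantProfile,
    protocol: StimulusProtocol,
    config: SimConfig,
    inactivation: bool = False,
) -> tuple[RecordingTrace, list[IdealizedPath]]:
    """Simulate paths for every channel in the patch and render the trace."""
    paths = [
        simulate_path(
            profile,
            protocol,
            config.duration_ms,
            seed=np.random.default_rng([int(config.seed), 0xA70, ch]),
            inactivation=inactivation,
        )
        for ch in range(config.n_channels)
    ]
    return render_trace(paths, profile, config, protocol), paths


def make_cohort(
    profile: VariantProfile,
    protocol: StimulusProtocol,
    config: SimConfig,
    n_cells: int,
    base_seed: int,
    inactivation: bool = False,
    return_paths: bool = False,
):
    """Simulate a cohort of patches with seeds base_seed..base_seed+n_cells-1."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    traces, all_paths = [], []
    for i in range(n_cells):
        cfg = replace(config, seed=base_seed + i)
        tr, paths = simulate_recording(profile, protocol, cfg, inactivation)
        traces.append(tr)
        all_paths.append(paths)
    return (traces, all_paths) if return_paths else traces
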