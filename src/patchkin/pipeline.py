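"""End-to-end workflows: trace -> conditioned trace -> amplitude model ->
idealized path -> per-recording metrics, plus cohort-level conveniences
(pressure and agonist fold changes, ensemble inactivation tau).

These functions chain the module-level operations exactly in the order a
patch-clamp analyst would: low-pass filter, baseline to the shut level,
all-point histogram and mixture fit (Po from peak areas), channel counting,
Viterbi idealization with dead-time imposition (occupancy, lifetimes, charge
flux), and finally the multi-channel Po adjustment.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import dwell as dw
from . import metrics as mx
from .idealize import AmplitudeMixture, estimate_channel_count, impose_dead_time, viterbi_idealize
from .preprocess import baseline_correct, butterworth_lowpass
from .profiles import VariantProfile
from .simulate import SimConfig, StimulusProtocol, make_cohort
from .trace import RecordingTrace
from .ensemble import EnsembleFit, align_average, fit_inactivation

__all__ = [
    "AnalysisConfig",
    "analyze_recording",
    "analyze_cohort",
    "simulate_cohort_metrics",
    "pressure_fold_change",
    "yoda1_fold_change",
    "ensemble_tau",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the analysis chain.

    ``expected_unitary_pA`` is the experimenter's prior for the open-level
    current at the recording voltage (used to seed the amplitude fit and to
    count stacked openings); when None it is taken from the fitted peaks.
    """

    filter_cutoff_hz: float = 2000.0
    filter_order: int = 4
    zero_phase: bool = True
    baseline_window_ms: float = 500.0
    bin_width_pA: float = 0.02
    n_amplitude_components: int = 3
    include_sub: bool = True
    expected_unitary_pA: float | None = -1.5
    expected_sub_fraction: float = 0.5
    dead_time_ms: float | None = None  # default 0.3 / cutoff
    expected_dwell_ms: float = 5.0
    lifetime_min_dwell_ms: float | None = None  # default 0.8 / cutoff


def _amplitude_model(trace: RecordingTrace, cfg: AnalysisConfig):
    init = None
    n_comp = cfg.n_amplitude_components
    if cfg.expected_unitary_pA is not None:
        u = cfg.expected_unitary_pA
        # simultaneous openings (samples beyond 1.5x the unitary level) mean
        # the patch holds >1 channel: extend the model with a stacked peak
        x = trace.current_pA
        beyond = (np.sign(u) * (x - np.median(x))) > 1.5 * abs(u)
        if beyond.mean() > 1e-4 and n_comp < 4:
            n_comp = 4
        init = {2: [0.0, u], 3: [0.0, cfg.expected_sub_fraction * u, u],
                4: [0.0, cfg.expected_sub_fraction * u, u, 2 * u]}[n_comp]
    mix = AmplitudeMixture(
        trace,
        n_components=n_comp,
        bin_width_pA=cfg.bin_width_pA,
        init_means_pA=init,
    )
    return mix.fit()


def analyze_recording(
    trace: RecordingTrace, config: AnalysisConfig | None = None
) -> mx.StateMetrics:
    """Run the full single-recording analysis chain and return its metrics."""
    cfg = config or AnalysisConfig()
    if cfg.filter_cutoff_hz < trace.sampling_rate_hz / 2:
        trace = butterworth_lowpass(trace, cfg.filter_cutoff_hz, cfg.filter_order, cfg.zero_phase)
    trace = baseline_correct(trace, cfg.baseline_window_ms)
    # burn-in excluded from amplitude statistics
    n_skip = min(int(trace.burn_in_ms / trace.dt_ms), len(trace) - 1)
    body = trace.replace(trace.current_pA[n_skip:])

    amp = _amplitude_model(body, cfg)
    model = amp.model
    po_hist = mx.po_from_areas(model, include_sub=cfg.include_sub)
    currents = mx.unitary_current(model)
    n_ch, no_open = estimate_channel_count(model, cfg.expected_unitary_pA)

    # state levels for the decoder: fitted means where available
    levels = {"shut": model.shut.mean_pA}
    cond = model.conducting
    if len(cond) >= 2:
        levels["sub"] = cond[0].mean_pA
        levels["open"] = cond[-1].mean_pA if n_ch == 1 else cond[1].mean_pA
    elif cond:
        levels["open"] = cond[-1].mean_pA
    else:  # no openings: decode against the expected level to confirm
        levels["open"] = cfg.expected_unitary_pA or -1.5
    if n_ch > 1:
        u = cfg.expected_unitary_pA or levels["open"]
        for k in range(2, n_ch + 1):
            levels[f"open{k}"] = k * u
    noise_sd = model.shut.sd_pA
    path = viterbi_idealize(trace, levels, noise_sd, expected_dwell_ms=cfg.expected_dwell_ms)
    dead = cfg.dead_time_ms if cfg.dead_time_ms is not None else 0.3 / cfg.filter_cutoff_hz * 1000
    path = impose_dead_time(path, dead)

    occ = dw.occupancy(path, states=list(levels))
    min_dwell = (
        cfg.lifetime_min_dwell_ms
        if cfg.lifetime_min_dwell_ms is not None
        else 0.8 / cfg.filter_cutoff_hz * 1000
    )
    life = dw.mean_lifetime(path, states=list(levels), min_dwell_ms=min_dwell)
    # summed-level time fractions -> per-channel Po
    level_fracs: dict[int, float] = {0: occ.get("shut", 0.0)}
    for lab, f in occ.items():
        if lab == "shut":
            continue
        k = int(lab[4:]) if lab.startswith("open") and len(lab) > 4 else 1
        level_fracs[k] = level_fracs.get(k, 0.0) + f
    po_adj = mx.adjust_po_multichannel(level_fracs, n_ch)

    erate = dw.elementary_charge_rate(currents, occ)
    g = mx.chord_conductance(currents["open"], trace.voltage_mV)
    pressures = [p for _s, _e, p in trace.pressure_segments]
    return mx.StateMetrics(
        po=po_hist if n_ch == 1 else po_adj,
        occupancy=occ,
        mean_lifetime_ms=life,
        unitary_current_pA=currents,
        conductance_pS=g,
        e_rate_per_s=erate,
        n_channels=n_ch,
        pressure_mmHg=pressures[0] if pressures else 0.0,
        yoda1=bool(trace.meta.get("yoda1", False)),
        voltage_mV=trace.voltage_mV,
        flags={
            "no_openings": no_open,
            "po_histogram": po_hist,
            "po_adjusted": po_adj,
            "amplitude_resid_rms": amp.resid_rms,
        },
    )


def analyze_cohort(
    traces: list[RecordingTrace],
    config: AnalysisConfig | None = None,
    extra_cols: dict | None = None,
) -> pd.DataFrame:
    """Per-recording metrics of a cohort as one tidy row per recording."""
    rows = []
    for i, tr in enumerate(traces):
        m = analyze_recording(tr, config)
        row = {"recording": i, "variant": tr.meta.get("profile_name", ""), **m.to_row()}
        if extra_cols:
            row.update(extra_cols)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort-level study workflows
# --------------------------------------------------------------------------
def simulate_cohort_metrics(
    profile: VariantProfile,
    pressure_mmHg: float,
    n_cells: int,
    base_seed: int,
    duration_s: float = 30.0,
    yoda1: bool = False,
    sim_config: SimConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Simulate a steady-state cohort at one pressure and analyze every patch."""
    duration_ms = duration_s * 1000.0
    protocol = StimulusProtocol.constant(pressure_mmHg, duration_ms, yoda1=yoda1)
    cfg = sim_config or SimConfig(duration_ms=duration_ms)
    cfg = replace(cfg, duration_ms=duration_ms)
    traces = make_cohort(profile, protocol, cfg, n_cells, base_seed)
    acfg = analysis_config
    if acfg is None:
        acfg = AnalysisConfig(expected_unitary_pA=profile.open_current_pA)
    return analyze_cohort(traces, acfg, extra_cols={"pressure_mmHg": pressure_mmHg, "yoda1": yoda1})


def pressure_fold_change(
    profile: VariantProfile,
    n_cells: int,
    base_seed: int = 1,
    pressure_mmHg: float = -30.0,
    duration_s: float = 30.0,
    **kw,
) -> tuple[float, pd.DataFrame]:
    """Cohort fold increase in Po: mean Po at pressure / mean Po at rest.

    The ratio of group means (not the mean of per-cell ratios) is used, which
    is robust to cells with near-zero resting Po.
    """
    df0 = simulate_cohort_metrics(profile, 0.0, n_cells, base_seed, duration_s, **kw)
    df1 = simulate_cohort_metrics(profile, pressure_mmHg, n_cells, base_seed, duration_s, **kw)
    fold = mx.fold_change(df1["po"].mean(), df0["po"].mean())
    df = pd.concat([df0, df1], ignore_index=True)
    return fold, df


def yoda1_fold_change(
    profile: VariantProfile,
    n_cells: int,
    base_seed: int = 1,
    pressure_mmHg: float = -30.0,
    duration_s: float = 30.0,
    **kw,
) -> tuple[float, pd.DataFrame]:
    """Agonist fold increase in Po at constant pressure (Yoda1 / baseline)."""
    df0 = simulate_cohort_metrics(profile, pressure_mmHg, n_cells, base_seed, duration_s, **kw)
    df1 = simulate_cohort_metrics(
        profile, pressure_mmHg, n_cells, base_seed, duration_s, yoda1=True, **kw
    )
    fold = mx.fold_change(df1["po"].mean(), df0["po"].mean())
    return fold, pd.concat([df0, df1], ignore_index=True)


def ensemble_tau(
    profile: VariantProfile,
    n_traces: int = 5,
    base_seed: int = 1,
    pressure_mmHg: float = -30.0,
    pre_ms: float = 150.0,
    step_ms: float = 700.0,
    n_channels: int = 150,
    noise_sd_pA: float = 0.15,
) -> EnsembleFit:
    """Ensemble inactivation tau from averaged pressure-step recordings.

    Each recording is a multi-channel ("macro-patch") step response with
    inactivation enabled; recordings are aligned on the step onset, averaged,
    and fitted with a single exponential from the post-onset peak to the step
    end.
    """
    protocol = StimulusProtocol.step(pre_ms, step_ms, pressure_mmHg)
    cfg = SimConfig(
        duration_ms=protocol.duration_ms, n_channels=n_channels, noise_sd_pA=noise_sd_pA
    )
    traces = make_cohort(profile, protocol, cfg, n_traces, base_seed, inactivation=True)
    avg = align_average(traces)
    return fit_inactivation(avg)
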