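"""Ensemble-averaged inactivation kinetics.

Pressure-step recordings are aligned at the step onset, averaged pointwise,
and the post-peak decay of the averaged current is fitted with a single
exponential I(t) = A exp(-t / tau) + C.  The fitted tau is the macroscopic
relaxation time constant of the channel population — not the single-channel
mean open time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .trace import RecordingTrace

__all__ = ["EnsembleFit", "align_average", "fit_inactivation", "InactivationDecay"]


@dataclass
class EnsembleFit:
    tau_ms: float
    amplitude_pA: float
    offset_pA: float
    window_ms: tuple[float, float]
    resid_rms_pA: float
    n_traces: int
    no_inactivation: bool = False

    def summary(self) -> str:
        flag = "  [no inactivation detected]" if self.no_inactivation else ""
        return (
            f"Ensemble inactivation fit over {self.n_traces} traces{flag}\n"
            f"  tau       = {self.tau_ms:8.2f} ms\n"
            f"  amplitude = {self.amplitude_pA:8.3f} pA\n"
            f"  offset    = {self.offset_pA:8.3f} pA\n"
            f"  window    = [{self.window_ms[0]:.1f}, {self.window_ms[1]:.1f}] ms\n"
            f"  resid RMS = {self.resid_rms_pA:8.4f} pA"
        )


def align_average(traces: list[RecordingTrace], onset_ms: float | None = None) -> RecordingTrace:
    """Pointwise mean of traces aligned at the pressure-step onset.

    All traces must share a sampling rate; with identical protocols (the
    normal case) the alignment is the identity and the output length is the
    shortest common length.
    """
    if len(traces) < 2:
        raise ValueError("ensemble averaging needs at least two traces")
    fs = {t.sampling_rate_hz for t in traces}
    if len(fs) != 1:
        raise ValueError(f"mismatched sampling rates: {fs}")
    onsets = []
    for t in traces:
        o = onset_ms if onset_ms is not None else t.pressure_onset_ms()
        onsets.append(0.0 if o is None else o)
    start_idx = [int(round(o / t.dt_ms)) for o, t in zip(onsets, traces)]
    # keep the longest shared window around the onset
    pre = min(start_idx)
    post = min(len(t) - s for t, s in zip(traces, start_idx))
    stack = np.stack(
        [t.current_pA[s - pre : s + post] for t, s in zip(traces, start_idx)]
    )
    avg = stack.mean(axis=0)
    t0 = traces[0]
    segs = [
        (max(a - (onsets[0] - pre * t0.dt_ms), 0.0), b - (onsets[0] - pre * t0.dt_ms), p)
        for a, b, p in t0.pressure_segments
    ]
    out = RecordingTrace(
        current_pA=avg,
        sampling_rate_hz=t0.sampling_rate_hz,
        voltage_mV=t0.voltage_mV,
        pressure_segments=[s for s in segs if s[1] > s[0]],
        filters=list(t0.filters),
        meta={"n_traces": len(traces), "aligned_onset_ms": pre * t0.dt_ms},
    )
    return out


class InactivationDecay:
    """Single-exponential decay model of an ensemble-averaged current.

    The fit window starts at the post-onset peak (extremum within
    ``peak_search_ms`` of the step onset) and ends at the pressure-step end,
    both overridable via ``window_ms``.
    """

    def __init__(
        self,
        avg_trace: RecordingTrace,
        window_ms: tuple[float, float] | None = None,
        peak_search_ms: float = 50.0,
    ):
        self.trace = avg_trace
        self.window_ms = window_ms
        self.peak_search_ms = peak_search_ms

    def _auto_window(self) -> tuple[float, float]:
        tr = self.trace
        onset = tr.pressure_onset_ms()
        if onset is None:
            onset = float(tr.meta.get("aligned_onset_ms", 0.0))
        end = tr.duration_ms
        for a, b, p in tr.pressure_segments:
            if p != 0:
                end = b
                break
        i0 = int(onset / tr.dt_ms)
        i1 = min(int((onset + self.peak_search_ms) / tr.dt_ms), len(tr) - 1)
        seg = tr.current_pA[i0 : i1 + 1]
        peak = i0 + int(np.argmax(np.abs(seg - np.median(tr.current_pA[:max(i0, 1)]))))
        return peak * tr.dt_ms, min(end, tr.duration_ms)

    def fit(self) -> EnsembleFit:
        tr = self.trace
        w = self.window_ms if self.window_ms is not None else self._auto_window()
        i0, i1 = int(w[0] / tr.dt_ms), int(w[1] / tr.dt_ms)
        if not 0 <= i0 < i1 <= len(tr):
            raise ValueError(f"fit window {w} outside trace")
        y = tr.current_pA[i0:i1]
        t = (np.arange(y.size)) * tr.dt_ms
        span = t[-1]
        c0 = float(np.mean(y[int(0.9 * y.size):]))
        a0 = float(y[0] - c0)
        # log-linear initialisation on the tail-referenced decay
        tau0 = span / 3
        if a0 != 0:
            z = (y - c0) / a0
            ok = z > 0.02
            if ok.sum() > 10:
                coef = np.polyfit(t[ok], np.log(z[ok]), 1)
                if coef[0] < 0:
                    tau0 = float(np.clip(-1.0 / coef[0], 1e-3, 100 * span))

        def model(tv, a, tau, c):
            return a * np.exp(-tv / tau) + c

        try:
            popt, _ = curve_fit(
                model,
                t,
                y,
                p0=[a0, tau0, c0],
                bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 1000 * span, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            popt = [a0, tau0, c0]
        a, tau, c = (float(v) for v in popt)
        resid = y - model(t, a, tau, c)
        noise = float(np.std(np.diff(y)) / np.sqrt(2)) if y.size > 10 else 0.0
        no_inact = (tau > 10 * span) or (abs(a) < 3 * noise)
        return EnsembleFit(
            tau_ms=tau,
            amplitude_pA=a,
            offset_pA=c,
            window_ms=(float(w[0]), float(w[1])),
            resid_rms_pA=float(np.sqrt(np.mean(resid**2))),
            n_traces=int(self.trace.meta.get("n_traces", 1)),
            no_inactivation=bool(no_inact),
        )


def fit_inactivation(
    avg_trace: RecordingTrace,
    window_ms: tuple[float, float] | None = None,
    peak_search_ms: float = 50.0,
) -> EnsembleFit:
    """Fit I(t) = A exp(-t/tau) + C to the post-peak ensemble decay."""
    return InactivationDecay(avg_trace, window_ms, peak_search_ms).fit()
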