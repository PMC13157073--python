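"""Trace conditioning before idealization: low-pass filtering and shut-state
baseline correction.

Two cutoff presets are provided for the Butterworth stage: ``acquisition``
(2 kHz, matching the recording bandwidth and used throughout the tests) and
``substate`` (20 Hz, a heavy smoothing preset for slow sub-level inspection
that destroys millisecond dwells and is therefore never applied before
dwell-time analysis).  The cutoff is always an explicit argument; the presets
only name the two conventional values.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .trace import RecordingTrace

__all__ = ["butterworth_lowpass", "baseline_correct", "CUTOFF_PRESETS"]

CUTOFF_PRESETS = {"acquisition": 2000.0, "substate": 20.0}


def butterworth_lowpass(
    trace: RecordingTrace,
    cutoff_hz: float,
    order: int = 4,
    zero_phase: bool = True,
) -> RecordingTrace:
    """Butterworth low-pass filter, zero-phase (forward-backward) by default.

    Zero-phase filtering is the default because dwell boundaries feed the
    kinetic statistics: a causal pass would delay every transition by the
    filter group delay and skew dwell durations.

    Raises
    ------
    ValueError
        If ``cutoff_hz`` is not inside (0, Nyquist).
    """
    nyq = trace.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = signal.butter(order, cutoff_hz, fs=trace.sampling_rate_hz, output="sos")
    if zero_phase:
        out = signal.sosfiltfilt(sos, trace.current_pA)
    else:
        out = signal.sosfilt(sos, trace.current_pA)
    return trace.replace(
        out,
        extra_filter={
            "type": "butterworth",
            "cutoff_hz": float(cutoff_hz),
            "order": int(order),
            "zero_phase": bool(zero_phase),
        },
    )


def _shut_mode(samples: np.ndarray, bin_width: float = 0.02) -> float:
    """Mode of the densest histogram peak — the shut level when the channel is
    shut most of the time (Po < 0.5).  Refined by parabolic interpolation."""
    lo, hi = samples.min(), samples.max()
    if hi - lo < bin_width:
        return float(np.median(samples))
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(samples, bins=edges)
    # light smoothing so single-bin noise does not move the argmax
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
    k = int(np.argmax(smooth))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if 0 < k < len(smooth) - 1:
        y0, y1, y2 = smooth[k - 1], smooth[k], smooth[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            k_frac = 0.5 * (y0 - y2) / denom
            return float(centers[k] + np.clip(k_frac, -0.5, 0.5) * bin_width)
    return float(centers[k])


def baseline_correct(trace: RecordingTrace, window_ms: float = 500.0) -> RecordingTrace:
    """Subtract a drifting shut-state baseline without compromising open levels.

    The shut level is tracked as the mode of the densest amplitude-histogram
    peak in overlapping windows (50% overlap) and interpolated linearly
    between window centres, then subtracted.  Because a mode estimate is used,
    openings (which occupy a minority of samples) do not pull the baseline,
    so the spacing between shut and open peaks is preserved.

    If the window is longer than the trace a single global correction is
    applied.
    """
    if window_ms <= 0:
        raise ValueError("window must be > 0 ms")
    x = trace.current_pA
    n = len(x)
    win = int(round(window_ms / trace.dt_ms))
    if win >= n:
        return trace.replace(x - _shut_mode(x))
    half = win // 2
    starts = np.arange(0, n - win + 1, half)
    if starts[-1] + win < n:
        starts = np.append(starts, n - win)
    centers = starts + win / 2.0
    modes = np.array([_shut_mode(x[s : s + win]) for s in starts])
    baseline = np.interp(np.arange(n), centers, modes)
    out = trace.replace(x - baseline)
    out.meta["baseline_window_ms"] = float(window_ms)
    return out
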