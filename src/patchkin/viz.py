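"""Quick-look plots: traces with idealization overlays, all-point amplitude
histograms with fitted peaks, and log-binned dwell histograms."""
from __future__ import annotations

import numpy as np

from .idealize import AmplitudeHistogram, AmplitudeModel, _mixture
from .path import IdealizedPath
from .trace import RecordingTrace

__all__ = ["plot_trace", "plot_amplitude_histogram", "plot_dwell_histogram"]


def plot_trace(trace: RecordingTrace, path: IdealizedPath | None = None, ax=None, max_points=200_000):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.5))
    step = max(1, len(trace) // max_points)
    ax.plot(trace.time_ms[::step] / 1000, trace.current_pA[::step], lw=0.3, color="0.4")
    if path is not None:
        t = trace.time_ms
        ax.plot(t[::step] / 1000, path.levels_at(t)[::step], lw=1.0, color="crimson")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("current (pA)")
    return ax


def plot_amplitude_histogram(
    hist: AmplitudeHistogram, model: AmplitudeModel | None = None, ax=None, log=True
):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.stairs(hist.counts, hist.bin_edges, fill=True, color="0.8")
    if model is not None:
        x = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 1000)
        params = []
        for c in model.components:
            if model.backend == "gaussian":
                amp = c.area * hist.n_samples * hist.bin_width / (c.sd_pA * np.sqrt(2 * np.pi))
            else:
                amp = c.area * hist.n_samples * hist.bin_width / (2 * c.sd_pA)
            params += [c.mean_pA, c.sd_pA, amp]
        ax.plot(x, _mixture(x, np.array(params), model.backend), color="crimson", lw=1)
    if log:
        ax.set_yscale("log")
        ax.set_ylim(bottom=0.5)
    ax.set_xlabel("current (pA)")
    ax.set_ylabel("count")
    return ax


def plot_dwell_histogram(dh, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.stairs(dh.counts, dh.bin_edges_ms, fill=True, color="0.8")
    ax.set_xscale("log")
    ax.set_xlabel("dwell (ms)")
    ax.set_ylabel("count")
    ax.set_title(dh.state)
    return ax
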