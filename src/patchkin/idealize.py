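"""Idealization: amplitude models and Viterbi decoding.

The route from a conditioned trace to kinetics is: all-point amplitude
histogram -> mixture fit of the conductance levels (Gaussian peaks by default,
two-sided exponential peaks as an alternative backend) -> channel counting ->
Viterbi most-probable state path under Gaussian emissions -> dead-time
imposition.  The amplitude model carries the quantities the open-probability
arithmetic needs: the shut (Ac) and conducting (Ao) areas and the unitary
current (shut-referenced open-peak mean).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage, signal
from scipy.optimize import curve_fit

from .path import IdealizedPath
from .trace import RecordingTrace

__all__ = [
    "AmplitudeHistogram",
    "AmplitudeComponent",
    "AmplitudeModel",
    "AmplitudeMixture",
    "allpoint_histogram",
    "fit_amplitude_model",
    "estimate_channel_count",
    "viterbi_idealize",
    "impose_dead_time",
]


# --------------------------------------------------------------------------
# all-point histogram
# --------------------------------------------------------------------------
@dataclass
class AmplitudeHistogram:
    bin_edges: np.ndarray  # pA, strictly increasing
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1 or np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative with len(edges) - 1 entries")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


def allpoint_histogram(
    trace: RecordingTrace | np.ndarray, bin_width_pA: float = 0.02
) -> AmplitudeHistogram:
    """All-point current-amplitude histogram with fixed bin width."""
    samples = trace.current_pA if isinstance(trace, RecordingTrace) else np.asarray(trace, float)
    if samples.size == 0:
        raise ValueError("cannot histogram an empty trace")
    if bin_width_pA <= 0:
        raise ValueError("bin width must be > 0")
    lo = np.floor(samples.min() / bin_width_pA) * bin_width_pA
    hi = np.ceil(samples.max() / bin_width_pA) * bin_width_pA
    if hi <= lo:
        hi = lo + bin_width_pA
    nbins = int(round((hi - lo) / bin_width_pA))
    counts, edges = np.histogram(samples, bins=nbins, range=(lo, hi))
    return AmplitudeHistogram(edges, counts)


# --------------------------------------------------------------------------
# amplitude mixture model
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class AmplitudeComponent:
    mean_pA: float
    sd_pA: float
    area: float  # fraction of samples
    degenerate: bool = False


@dataclass
class AmplitudeModel:
    """Fitted mixture of conductance-level peaks, ordered by |mean|.

    The component nearest 0 pA is the shut level; its area is Ac and the
    summed area of all other components is Ao.
    """

    components: list[AmplitudeComponent]
    backend: str = "gaussian"
    n_requested: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        comps = sorted(self.components, key=lambda c: abs(c.mean_pA))
        total = sum(c.area for c in comps)
        if total <= 0:
            raise ValueError("component areas must sum to a positive value")
        self.components = [
            AmplitudeComponent(c.mean_pA, c.sd_pA, c.area / total, c.degenerate) for c in comps
        ]
        if any(c.sd_pA <= 0 for c in self.components):
            raise ValueError("component SDs must be > 0")

    @property
    def shut(self) -> AmplitudeComponent:
        return self.components[0]

    @property
    def conducting(self) -> list[AmplitudeComponent]:
        return [c for c in self.components[1:] if not c.degenerate]

    @property
    def area_shut(self) -> float:
        return self.shut.area

    @property
    def area_conducting(self) -> float:
        return sum(c.area for c in self.conducting)

    def means(self) -> np.ndarray:
        return np.array([c.mean_pA for c in self.components])


class AmplitudeMixtureResults:
    """Results wrapper for a fitted amplitude mixture."""

    def __init__(self, model: AmplitudeModel, histogram: AmplitudeHistogram, resid_rms: float):
        self.model = model
        self.histogram = histogram
        self.resid_rms = resid_rms

    def summary(self) -> str:
        lines = [
            f"Amplitude mixture ({self.model.backend}), "
            f"{len(self.model.components)} components, "
            f"{self.histogram.n_samples} samples, residual RMS {self.resid_rms:.1f} counts",
            f"{'level':>8} {'mean pA':>9} {'sd pA':>7} {'area':>7}",
        ]
        names = ["shut"] + [f"level{i}" for i in range(1, len(self.model.components))]
        for name, c in zip(names, self.model.components):
            flag = " (degenerate)" if c.degenerate else ""
            lines.append(f"{name:>8} {c.mean_pA:9.3f} {c.sd_pA:7.3f} {c.area:7.4f}{flag}")
        return "\n".join(lines)


def _peak_shape(x, mean, sd, amp, backend):
    if backend == "gaussian":
        return amp * np.exp(-0.5 * ((x - mean) / sd) ** 2)
    # two-sided exponential peak (the alternative least-squares backend for
    # log-scale amplitude histograms)
    return amp * np.exp(-np.abs(x - mean) / sd)


def _mixture(x, params, backend):
    y = np.zeros_like(x)
    for mean, sd, amp in params.reshape(-1, 3):
        y = y + _peak_shape(x, mean, sd, amp, backend)
    return y


def _detect_peaks(hist: AmplitudeHistogram, max_peaks: int) -> list[tuple[float, float]]:
    """(location, height) of candidate level peaks on the smoothed log counts."""
    logc = np.log10(hist.counts + 1.0)
    smooth = ndimage.gaussian_filter1d(logc, sigma=2.0)
    idx, props = signal.find_peaks(smooth, prominence=0.15, distance=5)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(smooth))])
        props = {"prominences": np.array([1.0])}
    order = np.argsort(props["prominences"])[::-1]
    idx = idx[order][:max_peaks]
    return [(float(hist.centers[i]), float(hist.counts[i])) for i in idx]


class AmplitudeMixture:
    """Least-squares mixture model of an all-point amplitude histogram.

    Parameters
    ----------
    data : RecordingTrace, ndarray or AmplitudeHistogram
    n_components : int
        Number of level peaks requested (2-4).  If peak detection finds
        fewer candidate peaks, the fit proceeds with the detected count and a
        warning; missing components are reported as degenerate.
    backend : {"gaussian", "exponential"}
        Peak shape.  Gaussian is the default; the exponential backend fits
        two-sided exponential peaks to the same histogram.
    init_means_pA : sequence of float, optional
        Known approximate level locations (e.g. 0, u/2, u from the expected
        unitary current) used to seed the fit instead of blind peak
        detection.  Peak detection remains the fallback.
    """

    def __init__(self, data, n_components: int = 2, backend: str = "gaussian",
                 bin_width_pA: float = 0.02, init_means_pA=None):
        if backend not in ("gaussian", "exponential"):
            raise ValueError("backend must be 'gaussian' or 'exponential'")
        if n_components not in (2, 3, 4):
            raise ValueError("n_components must be 2, 3 or 4")
        self.histogram = (
            data if isinstance(data, AmplitudeHistogram) else allpoint_histogram(data, bin_width_pA)
        )
        self.n_components = n_components
        self.backend = backend
        self.init_means_pA = None if init_means_pA is None else list(init_means_pA)

    def fit(self) -> AmplitudeMixtureResults:
        hist = self.histogram
        x, y = hist.centers, hist.counts.astype(float)
        if self.init_means_pA is not None:
            lo_x, hi_x = x.min(), x.max()
            means = [m for m in self.init_means_pA if lo_x <= m <= hi_x]
            peaks = [
                (float(m), float(y[int(np.argmin(np.abs(x - m)))])) for m in means
            ][: self.n_components]
        else:
            peaks = _detect_peaks(hist, self.n_components)
        n_found = len(peaks)
        if n_found == 0:
            peaks = _detect_peaks(hist, self.n_components)
            n_found = len(peaks)
        if n_found < self.n_components:
            warnings.warn(
                f"only {n_found} amplitude peaks detected; fitting {n_found} components",
                stacklevel=2,
            )
        sd0 = max(3 * hist.bin_width, 0.25 * np.std(x[y > 0]))
        p0, lo, hi = [], [], []
        span = x.max() - x.min()
        seeded = self.init_means_pA is not None
        for mean, height in peaks:
            p0 += [mean, sd0, max(height, 1.0)]
            if seeded:  # keep each component near its known level
                m_lo, m_hi = mean - 0.35, mean + 0.35
            else:
                m_lo, m_hi = x.min() - hist.bin_width, x.max() + hist.bin_width
            lo += [m_lo, hist.bin_width / 4, 0.0]
            hi += [m_hi, span, 10.0 * y.max() + 10]
        sigma = np.sqrt(y + 1.0)  # Poisson weighting

        def f(xv, *params):
            return _mixture(xv, np.asarray(params), self.backend)

        try:
            popt, _ = curve_fit(
                f, x, y, p0=p0, bounds=(lo, hi), sigma=sigma, maxfev=20000
            )
        except RuntimeError:
            popt = np.asarray(p0)
        comps = []
        for mean, sd, amp in popt.reshape(-1, 3):
            if self.backend == "gaussian":
                raw_area = amp * sd * np.sqrt(2 * np.pi) / hist.bin_width
            else:
                raw_area = 2.0 * amp * sd / hist.bin_width
            comps.append((mean, sd, raw_area / max(hist.n_samples, 1)))
        # degenerate components: vanishing area or duplicated location
        comps.sort(key=lambda c: abs(c[0]))
        out: list[AmplitudeComponent] = []
        for mean, sd, area in comps:
            dup = any(
                abs(mean - c.mean_pA) < max(sd, c.sd_pA) and not c.degenerate for c in out
            )
            degen = area < 1e-3 or dup
            out.append(AmplitudeComponent(mean, sd, max(area, 1e-12), degenerate=degen))
        model = AmplitudeModel(out, backend=self.backend, n_requested=self.n_components)
        resid = y - _mixture(x, popt, self.backend)
        return AmplitudeMixtureResults(model, hist, float(np.sqrt(np.mean(resid**2))))


def fit_amplitude_model(
    data, n_components: int = 2, backend: str = "gaussian", bin_width_pA: float = 0.02
) -> AmplitudeModel:
    """Convenience wrapper: fit and return the :class:`AmplitudeModel`."""
    return AmplitudeMixture(data, n_components, backend, bin_width_pA).fit().model


def estimate_channel_count(
    model: AmplitudeModel, unitary_current_pA: float | None = None
) -> tuple[int, bool]:
    """Number of channels in the patch from stacked open peaks.

    N is the largest k for which a fitted component sits at ~k x unitary
    current (tolerance 25% of the unitary spacing).  Components at
    intermediate (sub-conductance) levels match no integer multiple and are
    ignored.  Returns ``(N, no_openings)``: patches with no conducting
    component report N = 1 with the flag set.
    """
    if unitary_current_pA is None:
        cond = model.conducting
        if not cond:
            return 1, True
        unitary_current_pA = cond[-1].mean_pA - model.shut.mean_pA
    if unitary_current_pA == 0:
        raise ValueError("unitary current must be nonzero")
    if not model.conducting:
        return 1, True
    tol = 0.25 * abs(unitary_current_pA)
    n = 0
    for c in model.conducting:
        rel = c.mean_pA - model.shut.mean_pA
        k = round(rel / unitary_current_pA)
        if k >= 1 and abs(rel - k * unitary_current_pA) <= tol:
            n = max(n, int(k))
    return (n, False) if n >= 1 else (1, True)


# --------------------------------------------------------------------------
# Viterbi decoding
# --------------------------------------------------------------------------
@njit(cache=True)
def _viterbi_kernel(obs, levels, noise_sd, log_trans):  # pragma: no cover - numba
    T = obs.shape[0]
    K = levels.shape[0]
    inv2s2 = 1.0 / (2.0 * noise_sd * noise_sd)
    delta = np.empty(K)
    delta_new = np.empty(K)
    back = np.empty((T, K), dtype=np.int8)
    for k in range(K):
        d = obs[0] - levels[k]
        delta[k] = -d * d * inv2s2
        back[0, k] = 0
    for t in range(1, T):
        for k in range(K):
            best = -1e300
            arg = 0
            for j in range(K):
                v = delta[j] + log_trans[j, k]
                if v > best:
                    best = v
                    arg = j
            d = obs[t] - levels[k]
            delta_new[k] = best - d * d * inv2s2
            back[t, k] = arg
        for k in range(K):
            delta[k] = delta_new[k]
    path = np.empty(T, dtype=np.int8)
    best = -1e300
    arg = 0
    for k in range(K):
        if delta[k] > best:
            best = delta[k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def viterbi_idealize(
    trace: RecordingTrace,
    levels_pA: dict[str, float],
    noise_sd_pA: float,
    stay_prob: dict[str, float] | float | None = None,
    expected_dwell_ms: float = 5.0,
    skip_burn_in: bool = True,
) -> IdealizedPath:
    """Most-probable state path under Gaussian emissions.

    Parameters
    ----------
    levels_pA : dict
        State label -> current level, typically the fitted amplitude-model
        means.
    noise_sd_pA : float
        Shared emission SD, conventionally the shut-component SD.
    stay_prob : dict, float or None
        Per-state self-transition probability per sample.  Default
        ``1 - dt / expected_dwell_ms`` for every state; the remaining mass is
        split uniformly over the other states.

    Returns
    -------
    IdealizedPath
        Adjacent identical states merged into dwells; first and last dwell
        flagged censored.
    """
    obs = trace.current_pA
    if not np.all(np.isfinite(obs)):
        raise ValueError("trace contains non-finite samples")
    if noise_sd_pA <= 0:
        raise ValueError("noise SD must be > 0")
    labels = list(levels_pA)
    K = len(labels)
    if K < 2:
        raise ValueError("need at least two states to idealize")
    dt = trace.dt_ms
    t0 = 0.0
    if skip_burn_in and trace.burn_in_ms > 0:
        n_skip = min(int(trace.burn_in_ms / dt), len(obs) - 1)
        obs = obs[n_skip:]
        t0 = n_skip * dt
    if stay_prob is None:
        stay = {lab: max(1.0 - dt / expected_dwell_ms, 0.5) for lab in labels}
    elif np.isscalar(stay_prob):
        stay = {lab: float(stay_prob) for lab in labels}
    else:
        stay = {lab: float(stay_prob[lab]) for lab in labels}
    log_trans = np.empty((K, K))
    for i, lab in enumerate(labels):
        p = stay[lab]
        if not 0 < p < 1:
            raise ValueError("stay probabilities must be in (0, 1)")
        off = (1.0 - p) / (K - 1)
        log_trans[i, :] = np.log(off)
        log_trans[i, i] = np.log(p)
    levels = np.array([levels_pA[lab] for lab in labels], dtype=float)
    idx = _viterbi_kernel(
        np.ascontiguousarray(obs, dtype=np.float64), levels, float(noise_sd_pA), log_trans
    )
    lab_arr = np.array(labels, dtype=object)[idx]
    lvl_arr = levels[idx]
    return IdealizedPath.from_samples(lab_arr, lvl_arr, dt, t0_ms=t0, source="viterbi")


def impose_dead_time(path: IdealizedPath, dead_time_ms: float) -> IdealizedPath:
    """Merge dwells shorter than the dead time into their longer neighbour.

    The dead time models the filter rise time (conventionally ~0.3 / cutoff):
    events briefer than it cannot be resolved and are absorbed.  Total
    duration is conserved and the event count never increases.
    """
    if dead_time_ms < 0:
        raise ValueError("dead time must be >= 0")
    if dead_time_ms == 0 or len(path) == 1:
        return path
    states = list(path.states)
    durs = list(path.duration_ms)
    levels = list(path.level_pA)
    changed = True
    while changed and len(durs) > 1:
        changed = False
        short = [i for i, d in enumerate(durs) if d < dead_time_ms]
        if not short:
            break
        i = min(short, key=lambda j: durs[j])
        left = durs[i - 1] if i > 0 else -1.0
        right = durs[i + 1] if i < len(durs) - 1 else -1.0
        j = i - 1 if left >= right else i + 1
        durs[j] += durs[i]
        del states[i], durs[i], levels[i]
        # coalesce neighbours that became identical
        k = 1
        while k < len(states):
            if states[k] == states[k - 1]:
                durs[k - 1] += durs[k]
                del states[k], durs[k], levels[k]
            else:
                k += 1
        changed = True
    starts = path.start_ms[0] + np.concatenate(([0.0], np.cumsum(durs[:-1])))
    return IdealizedPath(
        states=np.array(states, dtype=object),
        start_ms=starts,
        duration_ms=np.array(durs),
        level_pA=np.array(levels),
        censored_first=path.censored_first,
        censored_last=path.censored_last,
        meta={**path.meta, "dead_time_ms": dead_time_ms},
    )
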