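"""Dwell-time analytics on idealized paths.

Occupancy is the time fraction per state over the analyzed interval (censored
edge dwells included, since they still occupy time); mean lifetimes average
uncensored dwells only, the standard control for edge bias.  Dwell-time
distributions are summarised with log-binned histograms and exponential
mixture fits, and per-state ion flux is expressed as elementary charges per
second, |i| / e0 scaled by the state's occupancy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import ELEMENTARY_CHARGE_C
from .path import IdealizedPath

__all__ = [
    "occupancy",
    "mean_lifetime",
    "dwell_histogram",
    "DwellHistogram",
    "fit_exponential_mixture",
    "ExponentialMixture",
    "elementary_charge_rate",
]


def occupancy(path: IdealizedPath, states: list[str] | None = None) -> dict[str, float]:
    """Fraction of analyzed time spent in each state; sums to 1."""
    total = path.duration_ms.sum()
    labels = states if states is not None else sorted(set(path.states))
    out = {}
    for lab in labels:
        out[lab] = float(path.duration_ms[path.states == lab].sum() / total)
    return out


def mean_lifetime(
    path: IdealizedPath, states: list[str] | None = None, min_dwell_ms: float = 0.0
) -> dict[str, float | None]:
    """Arithmetic mean of uncensored dwell durations per state (ms).

    States visited only in censored edge dwells (or never) report ``None``.

    ``min_dwell_ms`` enables the truncated-exponential estimator
    ``mean(d | d >= c) - c``: dwells below the threshold are excluded and the
    threshold subtracted, which is unbiased for exponential dwells
    (memorylessness) while rejecting the sub-resolution artifact dwells that
    filtered level transitions leave behind.
    """
    labels = states if states is not None else sorted(set(path.states))
    out: dict[str, float | None] = {}
    for lab in labels:
        d = path.dwells(lab)
        if min_dwell_ms > 0:
            d = d[d >= min_dwell_ms]
            out[lab] = float(d.mean() - min_dwell_ms) if d.size else None
        else:
            out[lab] = float(d.mean()) if d.size else None
    return out


@dataclass
class DwellHistogram:
    bin_edges_ms: np.ndarray  # logarithmic bins
    counts: np.ndarray
    state: str

    @property
    def centers_ms(self) -> np.ndarray:
        return np.sqrt(self.bin_edges_ms[:-1] * self.bin_edges_ms[1:])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_low_ms": self.bin_edges_ms[:-1],
                "bin_high_ms": self.bin_edges_ms[1:],
                "count": self.counts,
            }
        )


def dwell_histogram(
    path: IdealizedPath, state: str, bins_per_decade: int = 10
) -> DwellHistogram:
    """Log-binned dwell-time histogram of the uncensored dwells in a state."""
    d = path.dwells(state)
    if d.size == 0:
        return DwellHistogram(np.array([1.0, 10.0]), np.array([0]), state)
    lo = np.floor(np.log10(d.min()) * bins_per_decade) / bins_per_decade
    hi = np.ceil(np.log10(d.max()) * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    nbins = int(round((hi - lo) * bins_per_decade))
    edges = 10 ** np.linspace(lo, hi, nbins + 1)
    edges[0] *= 1 - 1e-12
    edges[-1] *= 1 + 1e-12
    counts, _ = np.histogram(d, bins=edges)
    return DwellHistogram(edges, counts, state)


@dataclass
class ExponentialMixtureResults:
    taus_ms: np.ndarray
    weights: np.ndarray
    loglik: float
    n_dwells: int
    converged: bool

    def summary(self) -> str:
        lines = [f"Exponential mixture, {len(self.taus_ms)} components, n = {self.n_dwells}"]
        for t, w in zip(self.taus_ms, self.weights):
            lines.append(f"  tau = {t:9.3f} ms   weight = {w:.4f}")
        return "\n".join(lines)


class ExponentialMixture:
    """Maximum-likelihood exponential mixture for dwell durations.

    A single component has the closed-form MLE (the sample mean); multi-
    component fits run EM from multiple quantile-spread starts and keep the
    best likelihood.  Fits with fewer than 5 dwells per parameter fall back
    to a single component with a warning.
    """

    def __init__(self, dwells_ms, n_components: int = 1, n_starts: int = 8, seed: int = 0):
        self.dwells = np.asarray(dwells_ms, dtype=float)
        if self.dwells.size == 0 or np.any(self.dwells <= 0):
            raise ValueError("dwells must be a non-empty array of positive durations")
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = n_components
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, max_iter: int = 500, tol: float = 1e-10) -> ExponentialMixtureResults:
        d = self.dwells
        k = self.n_components
        if d.size < 5 * (2 * k - 1) and k > 1:
            warnings.warn(
                f"{d.size} dwells is too few for {k} exponential components; fitting 1",
                stacklevel=2,
            )
            k = 1
        if k == 1:
            tau = float(d.mean())
            ll = float(np.sum(-np.log(tau) - d / tau))
            return ExponentialMixtureResults(np.array([tau]), np.array([1.0]), ll, d.size, True)
        rng = np.random.default_rng(self.seed)
        best = None
        qs = np.quantile(d, np.linspace(0.15, 0.85, k))
        for s in range(self.n_starts):
            taus = qs * rng.uniform(0.3, 3.0, size=k) if s else qs.copy()
            w = np.full(k, 1.0 / k)
            ll_old = -np.inf
            conv = False
            for _ in range(max_iter):
                dens = w[None, :] / taus[None, :] * np.exp(-d[:, None] / taus[None, :])
                tot = dens.sum(axis=1)
                tot[tot <= 0] = 1e-300
                ll = float(np.log(tot).sum())
                resp = dens / tot[:, None]
                nk = resp.sum(axis=0)
                nk[nk <= 0] = 1e-12
                w = nk / d.size
                taus = (resp * d[:, None]).sum(axis=0) / nk
                taus = np.clip(taus, 1e-9, None)
                if abs(ll - ll_old) < tol * (1 + abs(ll)):
                    conv = True
                    break
                ll_old = ll
            if best is None or ll > best[0]:
                best = (ll, taus.copy(), w.copy(), conv)
        ll, taus, w, conv = best
        order = np.argsort(taus)
        return ExponentialMixtureResults(taus[order], w[order], ll, d.size, conv)


def fit_exponential_mixture(
    dwells_ms, n_components: int = 1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper returning (taus_ms, weights), taus ascending."""
    res = ExponentialMixture(dwells_ms, n_components, seed=seed).fit()
    return res.taus_ms, res.weights


def elementary_charge_rate(
    unitary_current_pA: dict[str, float],
    state_occupancy: dict[str, float],
    conditional: bool = False,
) -> dict[str, float]:
    """Ion flux per channel as elementary charges per second, per state.

    The primary definition is occupancy-scaled flux: e_rate(state) =
    occupancy * |i| / e0, so states the channel rarely visits contribute
    little.  With ``conditional=True`` the occupancy factor is dropped and
    the rate is the flux while dwelling in the state.  The ``total`` entry
    sums the conducting states.
    """
    out = {}
    for state, i_pA in unitary_current_pA.items():
        occ = 1.0 if conditional else state_occupancy.get(state, 0.0)
        out[state] = float(occ * abs(i_pA) * 1e-12 / ELEMENTARY_CHARGE_C)
    out["total"] = float(sum(v for k, v in out.items() if k != "total"))
    return out
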