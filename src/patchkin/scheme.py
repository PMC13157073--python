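"""Continuous-time Markov gating schemes for mechanosensitive channels.

A gating scheme is a labelled set of conductance states (shut, sub-conductance,
open, optionally inactivated) together with a generator matrix ``Q`` of
transition rates in s^-1, ``Q[i, j]`` being the rate from state ``i`` to state
``j`` and the diagonal the negative row sum.  Schemes are either written down
directly or solved from measurable targets — the stationary occupancy of each
state and its mean lifetime — which is how the packaged variant profiles are
built from published group values.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GatingState",
    "KineticScheme",
    "stationary_distribution",
    "calibrate_rates_to_targets",
    "scale_opening_rates",
    "CalibrationError",
]

#: canonical ordering of conducting states in a calibrated scheme
STATE_ORDER = ("shut", "sub", "open")

KNOWN_LABELS = frozenset({"shut", "sub", "open", "inactivated"})


class CalibrationError(ValueError):
    """Raised when no nonnegative rate matrix can reproduce the targets."""


@dataclass(frozen=True)
class GatingState:
    """A conductance level of the channel.

    Parameters
    ----------
    label : str
        One of ``shut``, ``sub``, ``open``, ``inactivated``.
    unitary_current_pA : float
        Current carried while the channel dwells in this state, at the
        reference holding voltage.  Inward current is negative; shut and
        inactivated states carry 0 pA.
    """

    label: str
    unitary_current_pA: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in KNOWN_LABELS:
            raise ValueError(f"unknown state label {self.label!r}")
        if self.label in ("shut", "inactivated") and self.unitary_current_pA != 0.0:
            raise ValueError(f"{self.label} state must carry 0 pA")


@dataclass
class KineticScheme:
    """States plus a generator matrix of transition rates (s^-1)."""

    states: tuple[GatingState, ...]
    Q: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        Q = np.array(self.Q, dtype=float)
        n = len(self.states)
        if Q.shape != (n, n):
            raise ValueError(f"rate matrix shape {Q.shape} != ({n}, {n})")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal transition rates must be >= 0")
        np.fill_diagonal(Q, -off.sum(axis=1))
        self.Q = Q
        labels = self.labels
        if labels.count("shut") != 1:
            raise ValueError("scheme must contain exactly one shut state")
        sub = [s for s in self.states if s.label == "sub"]
        opens = [s for s in self.states if s.label == "open"]
        if sub and opens and opens[0].unitary_current_pA != 0:
            if abs(sub[0].unitary_current_pA) >= abs(opens[0].unitary_current_pA):
                raise ValueError("|sub current| must be < |open current|")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def levels_pA(self) -> np.ndarray:
        return np.array([s.unitary_current_pA for s in self.states])

    def exit_rates(self) -> np.ndarray:
        """Total leaving rate of each state (s^-1)."""
        return -np.diag(self.Q)

    def mean_lifetimes_ms(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1000.0 / self.exit_rates()

    def active_subscheme(self) -> "KineticScheme":
        """Scheme restricted to the non-inactivated states."""
        keep = [i for i, s in enumerate(self.states) if s.label != "inactivated"]
        if len(keep) == len(self.states):
            return self
        idx = np.ix_(keep, keep)
        return KineticScheme(tuple(self.states[i] for i in keep), self.Q[idx])


def _check_connected(Q: np.ndarray) -> None:
    adj = (Q > 0) | (Q.T > 0)
    np.fill_diagonal(adj, False)
    n_comp, _ = connected_components(adj, directed=False)
    if Q.shape[0] > 1 and n_comp != 1:
        raise ValueError("rate graph is not connected among non-inactivated states")


def stationary_distribution(scheme: KineticScheme) -> np.ndarray:
    """Stationary probability vector pi with pi @ Q = 0 and sum(pi) = 1.

    The inactivated state (if present) is excluded: the stationary law is that
    of the gating process conditioned on being available.
    """
    sub = scheme.active_subscheme()
    Q = sub.Q
    if np.allclose(Q, 0.0):
        raise ValueError("all-zero rate matrix has no unique stationary law")
    _check_connected(Q)
    n = Q.shape[0]
    # solve pi Q = 0, sum pi = 1 as an augmented least-squares system
    A = np.vstack([Q.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    if len(sub.states) != len(scheme.states):
        # map back onto the full state tuple with 0 on inactivated
        full = np.zeros(len(scheme.states))
        j = 0
        for i, s in enumerate(scheme.states):
            if s.label != "inactivated":
                full[i] = pi[j]
                j += 1
        return full
    return pi


def _two_state_scheme(
    states: tuple[GatingState, GatingState],
    occ: np.ndarray,
    life_ms: tuple[float | None, float | None],
) -> KineticScheme:
    l1, l2 = life_ms
    if l1 is None and l2 is None:
        raise CalibrationError("at least one mean lifetime is required")
    if l2 is None:
        l2 = l1 * occ[1] / occ[0]  # stationary flux balance
    if l1 is None:
        l1 = l2 * occ[0] / occ[1]
    r1, r2 = 1000.0 / l1, 1000.0 / l2
    if not np.isclose(occ[0] * r1, occ[1] * r2, rtol=1e-9):
        raise CalibrationError(
            "two-state targets violate flux balance: occupancy/lifetime of "
            f"{states[0].label} and {states[1].label} imply unequal exchange fluxes"
        )
    Q = np.array([[-r1, r1], [r2, -r2]])
    return KineticScheme(states, Q)


def calibrate_rates_to_targets(
    target_occupancy: dict[str, float],
    target_mean_lifetime_ms: dict[str, float | None],
    state_currents_pA: dict[str, float] | None = None,
) -> KineticScheme:
    """Solve a gating scheme whose stationary occupancies and mean lifetimes
    match the targets exactly.

    Parameters
    ----------
    target_occupancy : dict
        Stationary time fraction per state label; must sum to 1.  Supported
        state sets: ``{shut, open}`` or ``{shut, sub, open}``.
    target_mean_lifetime_ms : dict
        Mean dwell (1 / exit rate) per state in ms.  For the two-state case one
        lifetime may be ``None`` and is derived from flux balance.
    state_currents_pA : dict, optional
        Unitary current attached to each state (default 0).

    Returns
    -------
    KineticScheme
        ``stationary_distribution(result)`` reproduces ``target_occupancy`` to
        1e-9 and each state's exit rate equals ``1000 / lifetime``.

    Raises
    ------
    CalibrationError
        If no nonnegative generator exists, naming the violated constraint.
    """
    labels = [s for s in STATE_ORDER if s in target_occupancy]
    if set(target_occupancy) - set(STATE_ORDER):
        raise CalibrationError(f"unsupported states {set(target_occupancy) - set(STATE_ORDER)}")
    occ = np.array([target_occupancy[s] for s in labels], dtype=float)
    if np.any(occ <= 0):
        raise CalibrationError("target occupancies must be strictly positive")
    if not np.isclose(occ.sum(), 1.0, atol=1e-9):
        raise CalibrationError(f"target occupancies sum to {occ.sum()}, not 1")
    cur = state_currents_pA or {}
    states = tuple(GatingState(s, cur.get(s, 0.0)) for s in labels)

    if len(labels) == 2:
        lifes = tuple(target_mean_lifetime_ms.get(s) for s in labels)
        return _two_state_scheme(states, occ, lifes)  # type: ignore[arg-type]
    if len(labels) != 3:
        raise CalibrationError("calibration supports 2 (shut/open) or 3 (shut/sub/open) states")

    life = np.array([target_mean_lifetime_ms[s] for s in labels], dtype=float)
    if np.any(~np.isfinite(life)) or np.any(life <= 0):
        raise CalibrationError("mean lifetimes must be finite and > 0")
    r = 1000.0 / life  # exit rates, s^-1
    flux = occ * r
    # a state's stationary efflux must be absorbable by the other states' effluxes
    for i, lab in enumerate(labels):
        cap = flux.sum() - flux[i]
        if flux[i] > cap * (1 + 1e-12):
            raise CalibrationError(
                f"infeasible targets: stationary flux out of '{lab}' "
                f"(occupancy/lifetime = {flux[i]:.4g}/s) exceeds the combined "
                f"flux capacity of the other states ({cap:.4g}/s); "
                f"lengthen the '{lab}' lifetime or raise the other occupancies"
            )
    p1, p2, p3 = occ  # shut, sub, open
    r1, r2, r3 = r
    # one-parameter family: x = rate(shut -> open)
    lo = max(0.0, (p3 * r3 - p2 * r2) / p1, r1 - p2 * r2 / p1)
    hi = min(r1, p3 * r3 / p1, (p1 * r1 - p2 * r2 + p3 * r3) / p1)
    if lo > hi + 1e-9 * r.max():
        raise CalibrationError("infeasible targets: empty feasible interval for shut->open rate")
    hi = max(hi, lo)  # boundary-feasible targets collapse to a point
    x = 0.5 * (lo + hi)
    q12 = r1 - x
    q23 = (p3 * r3 - p1 * x) / p2
    q21 = r2 - q23
    q31 = (p1 * r1 - p2 * r2 + p3 * r3 - p1 * x) / p3
    q32 = r3 - q31
    Q = np.array(
        [
            [0.0, q12, x],
            [q21, 0.0, q23],
            [q31, q32, 0.0],
        ]
    )
    Q[(Q < 0) & (Q > -1e-9 * r.max())] = 0.0  # clip rounding negatives
    scheme = KineticScheme(states, Q)
    pi = stationary_distribution(scheme)
    if not np.allclose(pi, occ, atol=1e-9):
        raise CalibrationError("internal solver error: stationary law does not match targets")
    return scheme


def scale_opening_rates(scheme: KineticScheme, factor: float) -> KineticScheme:
    """Return a scheme with every rate leaving the shut state multiplied.

    This is the agonist / pressure model used by the simulator: stimuli that
    stabilise conducting conformations are encoded as a multiplicative factor
    on the shut -> sub and shut -> open opening rates, leaving conductances and
    the closing rates untouched.
    """
    if factor <= 0:
        raise ValueError("rate factor must be > 0")
    Q = scheme.Q.copy()
    i = scheme.index("shut")
    row = Q[i].copy()
    row[i] = 0.0
    Q[i] = row * factor
    return KineticScheme(scheme.states, Q)
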