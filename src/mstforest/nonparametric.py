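"""Counting-process estimators for multistate event-history data.

Implements the per-transition Nelson-Aalen cumulative-hazard estimator
(with left truncation, needed for clock-forward transitions out of
non-initial states), the Aalen-Johansen product-integral estimator of the
transition probability matrix P(s, t), the closed-form Markov illness-death
transition probabilities, and the reverse Kaplan-Meier estimator of the
censoring survival G used for inverse-probability-of-censoring weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .data import TransitionDataset, TransitionStructure


class EstimationError(ValueError):
    pass


@dataclass
class CumulativeHazard:
    """Right-continuous step estimate of a cumulative transition hazard.

    ``A(s, t)`` is the sum of increments at jump times u with s < u <= t;
    additivity A(s, t) = A(s, u) + A(u, t) holds by construction.
    """

    times: np.ndarray
    increments: np.ndarray
    transition: tuple[int, int] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.increments = np.asarray(self.increments, dtype=float)
        if len(self.times) != len(self.increments):
            raise EstimationError("times and increments must share length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise EstimationError("jump times must be strictly increasing")
        if np.any(self.increments < 0):
            raise EstimationError("hazard increments must be nonnegative")
        self._cum = np.cumsum(self.increments)
        self._logsurv_ok = np.all(self.increments < 1.0)
        with np.errstate(divide="ignore"):
            self._surv = np.cumprod(1.0 - np.clip(self.increments, 0.0, 1.0))

    def cumulative(self, t) -> np.ndarray | float:
        """A(0, t] evaluated at scalar or array t."""
        return _step_eval(self.times, self._cum, t, fill=0.0)

    def evaluate(self, s: float, t: float) -> float:
        """A(s, t) = A(0, t) - A(0, s)."""
        return float(self.cumulative(t)) - float(self.cumulative(s))

    def survival(self, t) -> np.ndarray | float:
        """Product-limit survival prod_{u<=t}(1 - dA(u))."""
        return _step_eval(self.times, self._surv, t, fill=1.0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, increment, cumulative) export for plotting."""
        return pd.DataFrame(
            {"time": self.times, "increment": self.increments, "cumulative": self._cum}
        )

    @classmethod
    def zero(cls, transition=None) -> "CumulativeHazard":
        return cls(np.empty(0), np.empty(0), transition)


def _step_eval(times, values, t, fill):
    """Right-continuous step-function evaluation with a pre-jump fill value."""
    t = np.asarray(t, dtype=float)
    if len(times) == 0:
        out = np.full(t.shape, fill)
        return out if out.shape else float(fill)
    idx = np.searchsorted(times, t, side="right")
    out = np.where(idx > 0, np.asarray(values)[np.maximum(idx - 1, 0)], fill)
    return out if out.shape else float(out)


def _risk_counts(times: np.ndarray, entries: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Number at risk just before each time in ``at``: #{entry < u <= time}.

    Because entry <= time row-wise, #{entry < u <= time} decomposes as
    #{time >= u} - #{entry >= u}, each a searchsorted on a sorted copy.
    """
    st = np.sort(times)
    se = np.sort(entries)
    n = len(st)
    return (n - np.searchsorted(st, at, side="left")) - (
        n - np.searchsorted(se, at, side="left")
    )


def nelson_aalen(td: TransitionDataset) -> CumulativeHazard:
    """Nelson-Aalen estimator sum dN(u)/Y(u) at observed event times.

    Y(u) counts rows with truncation entry < u <= time, which reduces to the
    plain at-risk count when all entries are zero (reset clock or initial
    state). A dataset with no events yields the zero function.
    """
    if td.n == 0:
        raise EstimationError("empty transition dataset")
    ev = td.status == 1
    if not ev.any():
        return CumulativeHazard.zero(td.transition)
    ev_times, counts = np.unique(td.time[ev], return_counts=True)
    risk = _risk_counts(td.time, td.entry, ev_times)
    if np.any(risk <= 0):
        raise EstimationError("event time with empty risk set (inconsistent truncation)")
    return CumulativeHazard(ev_times, counts / risk, td.transition)


class CensoringSurvival:
    """Kaplan-Meier estimate of the censoring survival G(t) with left limits.

    Fitted with the roles of event and censoring reversed; used to build the
    IPCW weights 1/G(t-) and 1/G(s).
    """

    def __init__(self, times: np.ndarray, values: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if np.any(np.diff(self.values) > 1e-12):
            raise EstimationError("censoring survival must be nonincreasing")

    def __call__(self, t) -> np.ndarray | float:
        return _step_eval(self.times, self.values, t, fill=1.0)

    def left(self, t) -> np.ndarray | float:
        """Left limit G(t-)."""
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:
            out = np.ones(t.shape)
            return out if out.shape else 1.0
        idx = np.searchsorted(self.times, t, side="left")
        out = np.where(idx > 0, self.values[np.maximum(idx - 1, 0)], 1.0)
        return out if out.shape else float(out)


def censoring_survival(time, status=None) -> CensoringSurvival:
    """Reverse Kaplan-Meier: censorings are the events.

    Accepts a :class:`TransitionDataset` or (time, status) arrays, where
    status 1 marks a true event (competing exits in a transition dataset
    count as censorings, matching their role in the separate approach).
    With no censoring, G is identically 1.
    """
    if isinstance(time, TransitionDataset):
        td = time
        time, status = td.time, td.status
    time = np.asarray(time, dtype=float)
    cens = np.asarray(status, dtype=int) == 0
    if not cens.any():
        return CensoringSurvival(np.empty(0), np.empty(0))
    c_times, c_counts = np.unique(time[cens], return_counts=True)
    risk = _risk_counts(time, np.zeros_like(time), c_times)
    surv = np.cumprod(1.0 - c_counts / risk)
    return CensoringSurvival(c_times, surv)


class TransitionProbabilityMatrix:
    """Aalen-Johansen product-integral estimate of P(s, t).

    P(s, t) = prod over pooled jump times u in (s, t] of {I + dA(u)}, where
    the factor at u has off-diagonal (h, j) entry dA_hj(u) and diagonal
    1 - sum_j dA_hj(u); factors are multiplied in increasing time order.
    Rows sum to one by construction; a factor with negative diagonal
    (total outgoing increment above one) is rejected.
    """

    def __init__(self, structure: TransitionStructure, times: np.ndarray, factors: np.ndarray):
        self.structure = structure
        self.times = np.asarray(times, dtype=float)
        self.factors = np.asarray(factors, dtype=float)

    @property
    def n_states(self) -> int:
        return self.structure.n_states

    def __call__(self, s: float, t: float) -> np.ndarray:
        if t < s:
            raise ValueError("require s <= t")
        i = np.searchsorted(self.times, s, side="right")
        j = np.searchsorted(self.times, t, side="right")
        P = np.eye(self.n_states)
        for k in range(i, j):
            P = P @ self.factors[k]
        return P

    def probability(self, s: float, t: float, from_state: int, to_state: int) -> float:
        P = self(s, t)
        return float(P[self.structure.state_index(from_state), self.structure.state_index(to_state)])

    def occupation_curve(self, s: float, from_state: int, grid) -> pd.DataFrame:
        """Tidy P(s, t) rows over a time grid for one origin state."""
        h = self.structure.state_index(from_state)
        rows = []
        for t in np.asarray(grid, dtype=float):
            P = self(s, t)
            rows.append([t, *P[h]])
        cols = ["time"] + [f"P_{from_state}{j}" for j in self.structure.states]
        return pd.DataFrame(rows, columns=cols)


def aalen_johansen(
    hazards: Mapping[tuple[int, int], CumulativeHazard],
    structure: TransitionStructure,
) -> TransitionProbabilityMatrix:
    """Assemble the product-integral P(s, t) from per-transition hazards.

    All transitions of the structure must be supplied (possibly as zero
    hazards); all hazards must live on the study clock.
    """
    missing = [tr for tr in structure.transitions if tr not in hazards]
    if missing:
        raise EstimationError(f"missing hazards for transitions {missing}")
    pooled = np.unique(np.concatenate([hazards[tr].times for tr in structure.transitions] + [np.empty(0)]))
    N = structure.n_states
    factors = np.tile(np.eye(N), (len(pooled), 1, 1))
    for (h, j), ch in hazards.items():
        hi, ji = structure.state_index(h), structure.state_index(j)
        pos = np.searchsorted(pooled, ch.times)
        factors[pos, hi, ji] += ch.increments
        factors[pos, hi, hi] -= ch.increments
    bad = np.nonzero(np.min(np.diagonal(factors, axis1=1, axis2=2), axis=1) < 0)[0]
    if len(bad):
        raise EstimationError(
            f"total outgoing hazard increment above 1 at time {pooled[bad[0]]:g}"
        )
    return TransitionProbabilityMatrix(structure, pooled, factors)


def aalen_johansen_from_datasets(
    datasets: Mapping[tuple[int, int], TransitionDataset],
    structure: TransitionStructure,
) -> TransitionProbabilityMatrix:
    """Convenience: Nelson-Aalen per transition, then the product integral."""
    hazards = {tr: nelson_aalen(td) for tr, td in datasets.items()}
    return aalen_johansen(hazards, structure)


def illness_death_closed_form(
    a12: Callable[[float], float],
    a13: Callable[[float], float],
    a23: Callable[[float], float],
    s: float,
    t: float,
    tol: float = 1e-8,
) -> dict[str, float]:
    """Markov illness-death transition probabilities from intensity functions.

    P11(s,t) = exp(-(A12 + A13)(s,t)), P22(s,t) = exp(-A23(s,t)) and
    P12(s,t) = int_s^t P11(s,u) a12(u) P22(u,t) du by adaptive quadrature;
    P13 follows by row conservation. Intensities must be nonnegative and
    integrable on [s, t].
    """
    if t < s:
        raise ValueError("require s <= t")
    for name, fn in (("a12", a12), ("a13", a13), ("a23", a23)):
        probe = np.linspace(s, t, 7) if t > s else [s]
        if any(fn(float(u)) < 0 for u in probe):
            raise ValueError(f"negative intensity {name} on [s, t]")
    if t == s:
        return {"P11": 1.0, "P22": 1.0, "P12": 0.0, "P13": 0.0}

    def cum(fn, a, b):
        if b <= a:
            return 0.0
        val, _ = quad(fn, a, b, epsabs=tol * 1e-2, epsrel=tol * 1e-2, limit=200)
        return val

    P11 = np.exp(-(cum(a12, s, t) + cum(a13, s, t)))
    P22 = np.exp(-cum(a23, s, t))

    def integrand(u):
        return (
            np.exp(-(cum(a12, s, u) + cum(a13, s, u)))
            * a12(u)
            * np.exp(-cum(a23, u, t))
        )

    P12, _ = quad(integrand, s, t, epsabs=tol, epsrel=tol, limit=200)
    return {"P11": float(P11), "P22": float(P22), "P12": float(P12), "P13": float(1.0 - P11 - P12)}
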