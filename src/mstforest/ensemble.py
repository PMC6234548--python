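"""Per-transition tree ensembles: bootstrap forests and recursively imputed trees.

The forest (MSRSF) averages terminal-node estimators over B bootstrap trees.
The recursively imputed variant (MSRIST) fits M extremely randomized trees on
the full training data, computes each censored row's ensemble-conditional
failure law, replaces censored rows by draws from it (an event before tau, or
censoring at tau), refits one tree per imputed dataset, and repeats for a
fixed number of cycles; the last cycle's M trees form the final ensemble.

Rows censored by a competing exit (the subject left the origin state towards
another destination) are never imputed: their time to this transition is
structurally unobservable under the separate approach.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import TransitionDataset
from .nonparametric import CumulativeHazard
from .tree import CovariateEncoder, MultistateTree, grow_bootstrap_tree, grow_ermt

FOREST = "forest"
RIST = "rist"

PROV_ORIGINAL = "original"
PROV_IMPUTED_EVENT = "imputed_event"
PROV_IMPUTED_TAU = "imputed_tau"
PROV_COMPETING = "competing_censored"


@dataclass
class TransitionEnsemble:
    """A fitted collection of trees for one transition, with an averaging API."""

    transition: tuple[int, int]
    clock: str
    trees: list[MultistateTree]
    method: str
    config: dict
    encoder: CovariateEncoder
    tau: float
    oob: list[np.ndarray] | None = None

    def __post_init__(self):
        pooled = [t.times for tree in self.trees for t in tree.terminals() if len(t.times)]
        self.grid = np.unique(np.concatenate(pooled)) if pooled else np.empty(0)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def split_variables(self) -> set[str]:
        out: set[str] = set()
        for tree in self.trees:
            out |= tree.split_variables()
        return out

    # -- averaged predictions -------------------------------------------
    def _encode(self, Z) -> np.ndarray:
        if isinstance(Z, np.ndarray):
            return Z
        if isinstance(Z, (dict, pd.Series)):
            Z = pd.DataFrame([dict(Z)])
        return self.encoder.transform(Z)

    def predict_cumhaz(self, Z, times, randomize_on=None, rng=None) -> np.ndarray:
        """Ensemble cumulative hazard, pointwise average over trees; (n, len(times))."""
        X = self._encode(Z)
        times = np.asarray(times, dtype=float)
        acc = np.zeros((len(X), len(times)))
        for tree in self.trees:
            acc += tree.chf_matrix(X, times, randomize_on=randomize_on, rng=rng)
        return acc / self.n_trees

    def predict_survival(self, Z, times, randomize_on=None, rng=None) -> np.ndarray:
        """Ensemble survival, average of per-tree product-limit curves."""
        X = self._encode(Z)
        times = np.asarray(times, dtype=float)
        acc = np.zeros((len(X), len(times)))
        for tree in self.trees:
            acc += tree.survival_matrix(X, times, randomize_on=randomize_on, rng=rng)
        return acc / self.n_trees

    def cumhaz_for(self, z) -> CumulativeHazard:
        """Averaged cumulative hazard of a single case as a step function."""
        grid = self.grid
        if len(grid) == 0:
            return CumulativeHazard.zero(self.transition)
        vals = self.predict_cumhaz(z, grid)[0]
        inc = np.diff(np.concatenate([[0.0], vals]))
        keep = inc > 0
        return CumulativeHazard(grid[keep], inc[keep], self.transition)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "transition": list(self.transition),
            "clock": self.clock,
            "method": self.method,
            "config": self.config,
            "tau": float(self.tau),
            "encoder": self.encoder.to_dict(),
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionEnsemble":
        trees = [MultistateTree.from_dict(t) for t in d["trees"]]
        return cls(
            tuple(d["transition"]),
            d["clock"],
            trees,
            d["method"],
            dict(d["config"]),
            CovariateEncoder.from_dict(d["encoder"]),
            float(d["tau"]),
        )


# ----------------------------------------------------------------------
# MSRSF
# ----------------------------------------------------------------------
def fit_msrsf(
    td: TransitionDataset,
    B: int = 1000,
    K: int | None = None,
    n0: int = 6,
    min_events: int = 6,
    n_cuts: int = 1,
    seed: int | np.random.SeedSequence = 0,
) -> TransitionEnsemble:
    """Multistate random survival forest for one transition.

    B bootstrap trees with log-rank splitting among K random candidates;
    predictions average the per-tree terminal estimators.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    encoder = CovariateEncoder(td.categorical).fit(td.covariates)
    trees, oob = [], []
    for child in ss.spawn(B):
        tree, oob_idx = grow_bootstrap_tree(
            td,
            K=K,
            n0=n0,
            min_events=min_events,
            n_cuts=n_cuts,
            rng=np.random.default_rng(child),
            encoder=encoder,
        )
        trees.append(tree)
        oob.append(oob_idx)
    config = {"B": B, "K": trees[0].params.K, "n0": n0, "min_events": min_events, "n_cuts": n_cuts}
    return TransitionEnsemble(td.transition, td.clock, trees, FOREST, config, encoder, td.tau, oob)


# ----------------------------------------------------------------------
# conditional survival + imputation (RIST machinery)
# ----------------------------------------------------------------------
@dataclass
class ConditionalLaw:
    """Discrete conditional failure law of a censored row beyond its time c.

    ``times`` carry the conditional event-time masses ``probs`` on the pooled
    jump grid restricted to (c, tau]; ``p_tau`` is the residual probability of
    remaining event-free, realized as censoring at tau. ``degenerate`` flags
    S(c) = 0, where the row is imputed at the first grid time after c.
    """

    times: np.ndarray
    probs: np.ndarray
    p_tau: float
    degenerate: bool = False


def conditional_survival(ensemble: TransitionEnsemble, z, c: float) -> ConditionalLaw:
    """Ensemble-conditional law S(t | T > c, z) on the pooled jump grid."""
    if c >= ensemble.tau:
        raise ValueError("censoring time must be below tau")
    laws = _conditional_laws(ensemble, pd.DataFrame([dict(z)]) if isinstance(z, (dict, pd.Series)) else z, np.array([c]))
    return laws[0]


def _conditional_laws(ensemble: TransitionEnsemble, Z, cens_times: np.ndarray) -> list[ConditionalLaw]:
    grid = ensemble.grid
    if len(grid) == 0:
        return [ConditionalLaw(np.empty(0), np.empty(0), 1.0) for _ in cens_times]
    S = ensemble.predict_survival(Z, grid)
    laws = []
    for i, c in enumerate(cens_times):
        after = grid > c
        idx = np.searchsorted(grid, c, side="right")
        Sc = float(S[i, idx - 1]) if idx > 0 else 1.0
        if Sc <= 0:
            t_next = grid[after][0] if after.any() else ensemble.tau
            laws.append(ConditionalLaw(np.array([t_next]), np.array([1.0]), 0.0, degenerate=True))
            continue
        seg = np.concatenate([[Sc], S[i, after]])
        mass = -np.diff(seg)
        probs = mass / Sc
        p_tau = max(0.0, 1.0 - float(probs.sum()))
        laws.append(ConditionalLaw(grid[after], probs, p_tau))
    return laws


@dataclass
class ImputedDataset:
    """A transition dataset with censored rows resolved, plus row provenance."""

    dataset: TransitionDataset
    provenance: np.ndarray

    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.provenance, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


def _imputable_mask(td: TransitionDataset) -> np.ndarray:
    return (td.status == 0) & ~td.competing


def impute_one_step(
    td: TransitionDataset,
    ensemble: TransitionEnsemble,
    rng: np.random.Generator | int | None = None,
    laws: Sequence[ConditionalLaw] | None = None,
) -> ImputedDataset:
    """Replace each imputable censored row by a draw from its conditional law.

    Outcomes are either an event at a grid time strictly beyond the original
    censoring time (status 1, time < tau possible) or censoring at tau.
    Observed events and competing-exit censorings are untouched.
    """
    rng = np.random.default_rng(rng)
    tau = td.tau
    time = td.time.copy()
    status = td.status.copy()
    provenance = np.full(td.n, PROV_ORIGINAL, dtype=object)
    provenance[td.competing] = PROV_COMPETING
    mask = _imputable_mask(td)
    idx = np.nonzero(mask)[0]
    if len(idx):
        if laws is None:
            laws = _conditional_laws(ensemble, td.covariates.iloc[idx], td.time[idx])
        for k, i in enumerate(idx):
            if td.time[i] >= tau:
                time[i], status[i] = tau, 0
                provenance[i] = PROV_IMPUTED_TAU
                continue
            law = laws[k]
            u = rng.random()
            cum = np.cumsum(law.probs)
            pos = int(np.searchsorted(cum, u, side="right"))
            if pos < len(law.times):
                time[i], status[i] = float(law.times[pos]), 1
                provenance[i] = PROV_IMPUTED_EVENT
            else:
                time[i], status[i] = tau, 0
                provenance[i] = PROV_IMPUTED_TAU
    return ImputedDataset(td.with_outcome(time, status), provenance)


# ----------------------------------------------------------------------
# MSRIST
# ----------------------------------------------------------------------
def fit_msrist(
    td: TransitionDataset,
    M: int = 50,
    K: int | None = None,
    nmin: int = 6,
    n_cycles: int = 5,
    n_cuts: int = 1,
    seed: int | np.random.SeedSequence = 0,
) -> TransitionEnsemble:
    """Recursively imputed multistate survival trees for one transition.

    Cycle 0 fits M extremely randomized trees on the raw data; each later
    cycle computes conditional laws from the current M trees, draws M
    independently imputed datasets and refits one tree per dataset. The final
    cycle's trees form the ensemble.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    encoder = CovariateEncoder(td.categorical).fit(td.covariates)
    cycle_seeds = ss.spawn(n_cycles)

    def fit_cycle0():
        return [
            grow_ermt(
                td,
                K=K,
                min_events=nmin,
                n_cuts=n_cuts,
                rng=np.random.default_rng(child),
                encoder=encoder,
            )
            for child in cycle_seeds[0].spawn(M)
        ]

    trees = fit_cycle0()
    n_imputable = int(_imputable_mask(td).sum())
    config = {"M": M, "K": trees[0].params.K, "nmin": nmin, "n_cycles": n_cycles, "n_cuts": n_cuts}
    for cycle in range(1, n_cycles):
        if n_imputable == 0:
            break  # fully observed: refits would reproduce the same law
        current = TransitionEnsemble(td.transition, td.clock, trees, RIST, config, encoder, td.tau)
        idx = np.nonzero(_imputable_mask(td))[0]
        laws = _conditional_laws(current, td.covariates.iloc[idx], td.time[idx])
        new_trees = []
        for child in cycle_seeds[cycle].spawn(M):
            rng = np.random.default_rng(child)
            imputed = impute_one_step(td, current, rng=rng, laws=laws)
            new_trees.append(
                grow_ermt(
                    imputed.dataset,
                    K=K,
                    min_events=nmin,
                    n_cuts=n_cuts,
                    rng=rng,
                    encoder=encoder,
                )
            )
        trees = new_trees
    config["cycles_run"] = min(n_cycles, 1 if n_imputable == 0 else n_cycles)
    return TransitionEnsemble(td.transition, td.clock, trees, RIST, config, encoder, td.tau)
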