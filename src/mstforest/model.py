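"""Model / Results surface tying per-transition ensembles into multistate predictions.

Two model classes mirror the statsmodels idiom: construct from a
:class:`~mstforest.data.MultistateDataset`, call ``fit(seed)`` and receive a
Results object carrying the fitted per-transition ensembles, a
``predict_transition_probabilities`` method assembling them through the
Aalen-Johansen product integral, a ``summary()`` table and JSON
save/load. A covariate-free Aalen-Johansen baseline exposes the same
prediction surface for benchmarking.
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data import (
    CLOCK_RESET,
    ENTRY_TIME_COVARIATE,
    MultistateDataset,
    TransitionStructure,
    extract_transition_dataset,
)
from .ensemble import TransitionEnsemble, fit_msrist, fit_msrsf
from .nonparametric import aalen_johansen, nelson_aalen

MARKOV = "markov"
SOJOURN_AUGMENTED = "sojourn_augmented"


class _MultistateModel:
    """Shared plumbing: transition-dataset extraction and config validation."""

    method = "base"

    def __init__(self, dataset: MultistateDataset, markov_mode: str = MARKOV):
        if markov_mode not in (MARKOV, SOJOURN_AUGMENTED):
            raise ValueError(f"unknown markov_mode {markov_mode!r}")
        self.dataset = dataset
        self.structure = dataset.structure
        self.markov_mode = markov_mode

    def transition_datasets(self) -> dict:
        augment = self.markov_mode == SOJOURN_AUGMENTED
        return {
            tr: extract_transition_dataset(self.dataset, tr, augment_sojourn=augment)
            for tr in self.structure.transitions
        }


class MultistateRandomForest(_MultistateModel):
    """Multistate random survival forest (MSRSF).

    Per transition: B bootstrap trees grown with log-rank splitting among
    K = floor(sqrt(p)) random candidate covariates (default), terminal-node
    minimum of ``min_events`` observed events and ``n0`` unique cases.
    """

    method = "msrsf"

    def __init__(
        self,
        dataset: MultistateDataset,
        B: int = 1000,
        K: int | None = None,
        min_events: int = 6,
        n0: int = 6,
        n_cuts: int = 1,
        markov_mode: str = MARKOV,
    ):
        super().__init__(dataset, markov_mode)
        if B < 1:
            raise ValueError("B must be at least 1")
        self.B, self.K, self.min_events, self.n0, self.n_cuts = B, K, min_events, n0, n_cuts

    def fit(self, seed: int = 0) -> "MultistateEnsembleResults":
        ss = np.random.SeedSequence(seed)
        tds = self.transition_datasets()
        children = ss.spawn(len(self.structure.transitions))
        ensembles = {
            tr: fit_msrsf(
                tds[tr],
                B=self.B,
                K=self.K,
                n0=self.n0,
                min_events=self.min_events,
                n_cuts=self.n_cuts,
                seed=child,
            )
            for tr, child in zip(self.structure.transitions, children)
        }
        return MultistateEnsembleResults(self, ensembles, seed)


class RecursivelyImputedTrees(_MultistateModel):
    """Multistate recursively imputed survival trees (MSRIST).

    Per transition: M extremely randomized trees per cycle, censored rows
    re-imputed from the ensemble-conditional failure law between cycles.
    """

    method = "msrist"

    def __init__(
        self,
        dataset: MultistateDataset,
        M: int = 50,
        K: int | None = None,
        nmin: int = 6,
        n_cycles: int = 5,
        n_cuts: int = 1,
        markov_mode: str = MARKOV,
    ):
        super().__init__(dataset, markov_mode)
        if n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        if M < 1:
            raise ValueError("M must be at least 1")
        self.M, self.K, self.nmin, self.n_cycles, self.n_cuts = M, K, nmin, n_cycles, n_cuts

    def fit(self, seed: int = 0) -> "MultistateEnsembleResults":
        ss = np.random.SeedSequence(seed)
        tds = self.transition_datasets()
        children = ss.spawn(len(self.structure.transitions))
        ensembles = {
            tr: fit_msrist(
                tds[tr],
                M=self.M,
                K=self.K,
                nmin=self.nmin,
                n_cycles=self.n_cycles,
                n_cuts=self.n_cuts,
                seed=child,
            )
            for tr, child in zip(self.structure.transitions, children)
        }
        return MultistateEnsembleResults(self, ensembles, seed)


class MultistateEnsembleResults:
    """Fitted per-transition ensembles with multistate prediction and export."""

    def __init__(self, model: _MultistateModel, ensembles: Mapping, seed: int):
        self.model = model
        self.structure: TransitionStructure = model.structure
        self.markov_mode = model.markov_mode
        self.ensembles: dict = dict(ensembles)
        self.seed = seed

    # ------------------------------------------------------------------
    def _prediction_z(self, z, transition, current_state, entry_offset) -> pd.DataFrame:
        row = dict(z)
        ens = self.ensembles[transition]
        if ENTRY_TIME_COVARIATE in ens.encoder.columns and ENTRY_TIME_COVARIATE not in row:
            row[ENTRY_TIME_COVARIATE] = float(entry_offset)
        return pd.DataFrame([row])

    def predict_transition_survival(self, transition, Z, times, randomize_on=None, rng=None) -> np.ndarray:
        """Per-transition ensemble survival on that transition's clock."""
        return self.ensembles[tuple(transition)].predict_survival(
            Z, times, randomize_on=randomize_on, rng=rng
        )

    def predict_cumulative_hazard(self, transition, Z, times, randomize_on=None, rng=None) -> np.ndarray:
        return self.ensembles[tuple(transition)].predict_cumhaz(
            Z, times, randomize_on=randomize_on, rng=rng
        )

    def predict_transition_probabilities(
        self,
        z,
        s: float,
        t: float,
        current_state: int | None = None,
        entry_offset: float = 0.0,
    ) -> pd.Series:
        """State-occupation probabilities P(X(t) = . | X(s) = h, z).

        Ensemble hazards are evaluated on each transition's clock -- reset
        clocks out of the current state are shifted by ``entry_offset`` (the
        study-clock entry time d into h); reset clocks out of downstream
        states are approximated by restarting their clock at s -- and
        assembled through the product integral over the pooled jump grid.
        """
        st = self.structure
        if t < s:
            raise ValueError("require s <= t")
        if current_state is None:
            current_state = st.initial
        hi = st.state_index(current_state)
        out = pd.Series(0.0, index=list(st.states))
        if current_state in st.absorbing or t == s:
            out[current_state] = 1.0
            return out
        # map each transition's jump grid to the study clock and pool
        per_tr = {}
        for tr in st.transitions:
            ens = self.ensembles[tr]
            if tr[0] == current_state:
                offset = entry_offset if ens.clock == CLOCK_RESET else 0.0
            else:
                offset = s if ens.clock == CLOCK_RESET else 0.0
            Z = self._prediction_z(z, tr, current_state, entry_offset)
            ch = ens.cumhaz_for(Z.iloc[0])
            study_times = ch.times + offset
            keep = (study_times > s) & (study_times <= t)
            per_tr[tr] = (study_times[keep], ch.increments[keep])
        pooled = np.unique(np.concatenate([v[0] for v in per_tr.values()] + [np.empty(0)]))
        N = st.n_states
        P = np.eye(N)
        if len(pooled):
            factors = np.tile(np.eye(N), (len(pooled), 1, 1))
            for (h, j), (times, inc) in per_tr.items():
                a, b = st.state_index(h), st.state_index(j)
                pos = np.searchsorted(pooled, times)
                factors[pos, a, b] += inc
                factors[pos, a, a] -= inc
            diag = np.min(np.diagonal(factors, axis1=1, axis2=2), axis=1)
            bad = np.nonzero(diag < 0)[0]
            if len(bad):
                raise ValueError(
                    f"total outgoing increment above 1 at study time {pooled[bad[0]]:g}"
                )
            for k in range(len(pooled)):
                P = P @ factors[k]
        out[:] = P[hi]
        return out

    # ------------------------------------------------------------------
    def summary(self) -> str:
        st = self.structure
        lines = []
        title = f"{type(self.model).__name__} results".center(72)
        lines.append(title)
        lines.append("=" * 72)
        lines.append(f"method: {self.model.method}    markov_mode: {self.markov_mode}    seed: {self.seed}")
        lines.append(
            f"states: {st.states}    transitions: {st.transitions}"
        )
        lines.append("-" * 72)
        rows = []
        for tr, ens in self.ensembles.items():
            terms = [len(t.terminals()) for t in ens.trees]
            rows.append(
                {
                    "transition": f"{tr[0]}->{tr[1]}",
                    "clock": ens.clock,
                    "trees": ens.n_trees,
                    "K": ens.config.get("K"),
                    "mean_terminals": round(float(np.mean(terms)), 1),
                    "tau": round(ens.tau, 3),
                }
            )
        lines.append(pd.DataFrame(rows).to_string(index=False))
        lines.append("=" * 72)
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "package_version": _pkg_version,
            "method": self.model.method,
            "markov_mode": self.markov_mode,
            "seed": self.seed,
            "structure": self.structure.to_dict(),
            "ensembles": {f"{h}->{j}": ens.to_dict() for (h, j), ens in self.ensembles.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "MultistateEnsembleResults":
        with open(path) as fh:
            d = json.load(fh)
        structure = TransitionStructure.from_dict(d["structure"])

        class _Loaded(_MultistateModel):
            method = d["method"]

            def __init__(self):
                self.dataset = None
                self.structure = structure
                self.markov_mode = d["markov_mode"]

        ensembles = {}
        for key, ed in d["ensembles"].items():
            h, j = key.split("->")
            ensembles[(int(h), int(j))] = TransitionEnsemble.from_dict(ed)
        return cls(_Loaded(), ensembles, d["seed"])


class AalenJohansenBaseline(_MultistateModel):
    """Covariate-free nonparametric baseline with the Results prediction surface."""

    method = "aalen_johansen"

    def fit(self, seed: int = 0) -> "AalenJohansenResults":
        tds = self.transition_datasets()
        hazards = {tr: nelson_aalen(td) for tr, td in tds.items()}
        return AalenJohansenResults(self, hazards, seed)


class AalenJohansenResults:
    """Marginal Nelson-Aalen hazards; predictions ignore covariates."""

    def __init__(self, model: AalenJohansenBaseline, hazards: Mapping, seed: int = 0):
        self.model = model
        self.structure = model.structure
        self.hazards: dict = dict(hazards)
        self.seed = seed
        self._clocks = {tr: model.structure.clock(tr) for tr in model.structure.transitions}

    def predict_transition_survival(self, transition, Z, times, **_) -> np.ndarray:
        ch = self.hazards[tuple(transition)]
        n = len(Z) if hasattr(Z, "__len__") else 1
        surv = np.asarray(ch.survival(np.asarray(times, dtype=float)))
        return np.tile(surv, (n, 1))

    def predict_cumulative_hazard(self, transition, Z, times, **_) -> np.ndarray:
        ch = self.hazards[tuple(transition)]
        n = len(Z) if hasattr(Z, "__len__") else 1
        vals = np.asarray(ch.cumulative(np.asarray(times, dtype=float)))
        return np.tile(vals, (n, 1))

    def predict_transition_probabilities(self, z, s, t, current_state=None, entry_offset=0.0) -> pd.Series:
        st = self.structure
        if any(c == CLOCK_RESET for c in self._clocks.values()):
            raise ValueError("the product-integral baseline requires forward clocks")
        tpm = aalen_johansen(self.hazards, st)
        if current_state is None:
            current_state = st.initial
        P = tpm(s, t)
        return pd.Series(P[st.state_index(current_state)], index=list(st.states))

    def summary(self) -> str:
        rows = [
            {"transition": f"{h}->{j}", "jumps": len(ch.times), "A(0,tau)": round(float(ch.cumulative(np.inf)), 4)}
            for (h, j), ch in self.hazards.items()
        ]
        return "Aalen-Johansen baseline\n" + pd.DataFrame(rows).to_string(index=False)
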