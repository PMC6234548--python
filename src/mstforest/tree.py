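"""Single multistate survival trees: log-rank splitting with random candidates.

Trees are grown per transition on that transition's risk set, in the
extremely-randomized style: at each node K candidate covariates are drawn
without replacement, each paired with random cut points (numeric) or a random
category subset (categorical); the candidate maximizing the two-sample
log-rank statistic between the daughters wins. Terminal nodes hold the
Nelson-Aalen cumulative hazard and its product-limit survival fitted on the
node's rows. Bootstrap variants (for forests) resample rows with replacement
and return the out-of-bag indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import TransitionDataset
from .nonparametric import CumulativeHazard, _risk_counts

NUMERIC = "numeric"
CATEGORICAL = "categorical"

#: code assigned to categorical levels unseen at fit time (routed right)
UNSEEN = -1


class CovariateEncoder:
    """Maps a symbolic covariate frame to a float code matrix for the tree engine.

    Numeric columns pass through; categorical columns are integer-coded by
    their sorted training levels. Levels unseen at transform time get code
    :data:`UNSEEN` and are routed to the right daughter at prediction time.
    """

    def __init__(self, categorical: Sequence[str] = ()):
        self.declared = tuple(categorical)
        self.columns: tuple[str, ...] = ()
        self.kinds: dict[str, str] = {}
        self.categories: dict[str, list] = {}

    def fit(self, cov: pd.DataFrame) -> "CovariateEncoder":
        self.columns = tuple(cov.columns)
        for c in self.columns:
            if c in self.declared or cov[c].dtype == object or cov[c].dtype == bool or isinstance(
                cov[c].dtype, pd.CategoricalDtype
            ):
                self.kinds[c] = CATEGORICAL
                self.categories[c] = sorted(pd.unique(cov[c]).tolist(), key=str)
            else:
                self.kinds[c] = NUMERIC
        return self

    def transform(self, cov: pd.DataFrame) -> np.ndarray:
        X = np.empty((len(cov), len(self.columns)), dtype=float)
        for k, c in enumerate(self.columns):
            if c not in cov.columns:
                raise KeyError(f"covariate {c!r} missing from prediction input")
            if self.kinds[c] == NUMERIC:
                X[:, k] = cov[c].to_numpy(dtype=float)
            else:
                lookup = {v: i for i, v in enumerate(self.categories[c])}
                X[:, k] = np.array([lookup.get(v, UNSEEN) for v in cov[c]], dtype=float)
        return X

    def fit_transform(self, cov: pd.DataFrame) -> np.ndarray:
        return self.fit(cov).transform(cov)

    def to_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "kinds": dict(self.kinds),
            "categories": {k: list(v) for k, v in self.categories.items()},
            "declared": list(self.declared),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateEncoder":
        enc = cls(d.get("declared", ()))
        enc.columns = tuple(d["columns"])
        enc.kinds = dict(d["kinds"])
        enc.categories = {k: list(v) for k, v in d["categories"].items()}
        return enc


@dataclass(frozen=True)
class SplitRule:
    """A binary split: numeric threshold (x <= thr goes left) or category subset."""

    index: int
    name: str
    kind: str
    threshold: float | None = None
    left_categories: frozenset | None = None
    statistic: float = 0.0

    def goes_left(self, x: np.ndarray) -> np.ndarray:
        if self.kind == NUMERIC:
            return x <= self.threshold
        return np.isin(x, list(self.left_categories))


class _Node:
    __slots__ = ("split", "left", "right", "times", "increments", "survival", "n_rows", "n_events")

    def __init__(self):
        self.split = None
        self.left = None
        self.right = None
        self.times = None
        self.increments = None
        self.survival = None
        self.n_rows = 0
        self.n_events = 0

    @property
    def is_terminal(self) -> bool:
        return self.split is None


def logrank_statistic(time, status, left_mask, entry=None) -> float:
    """Two-sample log-rank chi-square (O - E)^2 / V with tie-corrected variance.

    Supports left truncation via ``entry`` (risk at u counts entry < u <= time).
    Returns 0 when the pooled data carry no events or the variance vanishes.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    left_mask = np.asarray(left_mask, dtype=bool)
    if entry is None:
        entry = np.zeros_like(time)
    entry = np.asarray(entry, dtype=float)
    if not left_mask.any() or left_mask.all():
        raise ValueError("both sides of the partition must be nonempty")
    ev = status == 1
    if not ev.any():
        return 0.0
    ev_times = np.unique(time[ev])
    d = _event_counts(time, ev, ev_times)
    d1 = _event_counts(time[left_mask], ev[left_mask], ev_times)
    Y = _risk_counts(time, entry, ev_times)
    Y1 = _risk_counts(time[left_mask], entry[left_mask], ev_times)
    ok = Y > 0
    d, d1, Y, Y1 = d[ok], d1[ok], Y[ok], Y1[ok]
    OmE = float(np.sum(d1 - d * Y1 / Y))
    vmask = Y > 1
    V = float(
        np.sum(
            d[vmask]
            * (Y1[vmask] / Y[vmask])
            * (1 - Y1[vmask] / Y[vmask])
            * (Y[vmask] - d[vmask])
            / (Y[vmask] - 1)
        )
    )
    if V <= 0:
        return 0.0
    return OmE * OmE / V


def _event_counts(time, ev, at):
    t = np.sort(time[ev])
    return np.searchsorted(t, at, side="right") - np.searchsorted(t, at, side="left")


def propose_splits(
    X: np.ndarray,
    kinds: Sequence[str],
    names: Sequence[str],
    K: int,
    rng: np.random.Generator,
    n_cuts: int = 1,
) -> list[SplitRule]:
    """Draw K candidate covariates with random cut points / category subsets.

    Covariates constant at the node yield no candidate; with every covariate
    constant the list is empty and the caller makes the node terminal.
    """
    p = X.shape[1]
    if K > p:
        raise ValueError("K cannot exceed the number of covariates")
    order = rng.permutation(p)[:K]
    candidates: list[SplitRule] = []
    for idx in order:
        col = X[:, idx]
        if kinds[idx] == NUMERIC:
            lo, hi = float(np.min(col)), float(np.max(col))
            if not lo < hi:
                continue
            for _ in range(n_cuts):
                thr = float(rng.uniform(lo, hi))
                if thr == lo:
                    continue
                candidates.append(SplitRule(int(idx), names[idx], NUMERIC, threshold=thr))
        else:
            levels = np.unique(col[col != UNSEEN]).astype(int)
            if len(levels) < 2:
                continue
            # uniformly random nonempty proper subset defines the left branch
            mask = int(rng.integers(1, 2 ** len(levels) - 1))
            left = frozenset(int(lv) for b, lv in enumerate(levels) if mask >> b & 1)
            candidates.append(SplitRule(int(idx), names[idx], CATEGORICAL, left_categories=left))
    return candidates


@dataclass(frozen=True)
class GrowthParams:
    """Stopping and randomization settings for one tree.

    ``min_events`` is the minimal number of this transition's events a
    terminal may hold (cause-specific, per the separate approach);
    ``min_unique`` the minimal number of unique original cases (bootstrap
    trees); ``K`` candidate covariates per node, default floor(sqrt(p));
    ``n_cuts`` random cut points per numeric candidate.
    """

    K: int
    min_events: int = 6
    min_unique: int = 1
    n_cuts: int = 1


def default_K(p: int) -> int:
    return max(1, int(np.sqrt(p)))


class MultistateTree:
    """A fitted recursive partition for one transition.

    Terminal payloads are Nelson-Aalen estimates on the node's rows.
    ``diagnostics['unseen_category_routed']`` counts prediction rows routed by
    the fixed unseen-level convention (right daughter).
    """

    def __init__(self, transition, root: _Node, encoder: CovariateEncoder, params: GrowthParams):
        self.transition = tuple(transition) if transition is not None else None
        self.root = root
        self.encoder = encoder
        self.params = params
        self.diagnostics = {"unseen_category_routed": 0}

    # -- structure views -------------------------------------------------
    def terminals(self) -> list[_Node]:
        out = []

        def rec(node):
            if node.is_terminal:
                out.append(node)
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    def split_variables(self) -> set[str]:
        out = set()

        def rec(node):
            if not node.is_terminal:
                out.add(node.split.name)
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    def depth(self) -> int:
        def rec(node):
            if node.is_terminal:
                return 0
            return 1 + max(rec(node.left), rec(node.right))

        return rec(self.root)

    # -- prediction ------------------------------------------------------
    def assign_terminals(
        self,
        X: np.ndarray,
        randomize_on: set[str] | None = None,
        rng: np.random.Generator | None = None,
    ) -> list[_Node]:
        """Vectorized drop-down: terminal node per row of the code matrix X.

        When ``randomize_on`` names covariates, any split on one of them
        routes each row to a uniformly random daughter (the VIMP mechanism).
        Unseen categorical codes go right and are tallied.
        """
        if randomize_on and rng is None:
            raise ValueError("randomize_on requires an rng")
        out: list[_Node | None] = [None] * len(X)
        idx_all = np.arange(len(X))

        def rec(node, idx):
            if len(idx) == 0:
                return
            if node.is_terminal:
                for i in idx:
                    out[i] = node
                return
            sp = node.split
            if randomize_on and sp.name in randomize_on:
                go_left = rng.random(len(idx)) < 0.5
            else:
                col = X[idx, sp.index]
                go_left = sp.goes_left(col)
                if sp.kind == CATEGORICAL:
                    unseen = col == UNSEEN
                    if unseen.any():
                        self.diagnostics["unseen_category_routed"] += int(unseen.sum())
                        go_left = go_left & ~unseen
            rec(node.left, idx[go_left])
            rec(node.right, idx[~go_left])

        rec(self.root, idx_all)
        return out  # type: ignore[return-value]

    def drop_down(self, z, randomize_on=None, rng=None):
        """Single-case drop-down returning (CumulativeHazard, survival step pair).

        ``z`` is a mapping/Series of covariate values covering the split
        variables. Returns the terminal's cumulative hazard and a
        (times, survival) pair.
        """
        row = pd.DataFrame([dict(z)])
        X = self.encoder.transform(row)
        node = self.assign_terminals(X, randomize_on=randomize_on, rng=rng)[0]
        ch = CumulativeHazard(node.times, node.increments, self.transition)
        return ch, (node.times, node.survival)

    def chf_matrix(self, X: np.ndarray, grid: np.ndarray, randomize_on=None, rng=None) -> np.ndarray:
        """Cumulative hazard of each row's terminal, evaluated on a time grid."""
        nodes = self.assign_terminals(X, randomize_on=randomize_on, rng=rng)
        return _payload_matrix(nodes, grid, survival=False)

    def survival_matrix(self, X: np.ndarray, grid: np.ndarray, randomize_on=None, rng=None) -> np.ndarray:
        nodes = self.assign_terminals(X, randomize_on=randomize_on, rng=rng)
        return _payload_matrix(nodes, grid, survival=True)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def rec(node):
            if node.is_terminal:
                return {
                    "terminal": True,
                    "times": [float(v) for v in node.times],
                    "increments": [float(v) for v in node.increments],
                    "n_rows": int(node.n_rows),
                    "n_events": int(node.n_events),
                }
            sp = node.split
            return {
                "terminal": False,
                "split": {
                    "index": sp.index,
                    "name": sp.name,
                    "kind": sp.kind,
                    "threshold": sp.threshold,
                    "left_categories": sorted(sp.left_categories) if sp.left_categories else None,
                    "statistic": float(sp.statistic),
                },
                "left": rec(node.left),
                "right": rec(node.right),
                "n_rows": int(node.n_rows),
                "n_events": int(node.n_events),
            }

        return {
            "transition": list(self.transition) if self.transition else None,
            "params": {
                "K": self.params.K,
                "min_events": self.params.min_events,
                "min_unique": self.params.min_unique,
                "n_cuts": self.params.n_cuts,
            },
            "encoder": self.encoder.to_dict(),
            "root": rec(self.root),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MultistateTree":
        def rec(nd):
            node = _Node()
            node.n_rows = nd.get("n_rows", 0)
            node.n_events = nd.get("n_events", 0)
            if nd["terminal"]:
                node.times = np.asarray(nd["times"], dtype=float)
                node.increments = np.asarray(nd["increments"], dtype=float)
                node.survival = np.cumprod(1.0 - np.clip(node.increments, 0.0, 1.0))
            else:
                sp = nd["split"]
                node.split = SplitRule(
                    sp["index"],
                    sp["name"],
                    sp["kind"],
                    threshold=sp["threshold"],
                    left_categories=frozenset(sp["left_categories"]) if sp["left_categories"] else None,
                    statistic=sp["statistic"],
                )
                node.left = rec(nd["left"])
                node.right = rec(nd["right"])
            return node

        params = GrowthParams(**d["params"])
        tree = cls(
            tuple(d["transition"]) if d["transition"] else None,
            rec(d["root"]),
            CovariateEncoder.from_dict(d["encoder"]),
            params,
        )
        return tree


def _payload_matrix(nodes: list[_Node], grid: np.ndarray, survival: bool) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    out = np.empty((len(nodes), len(grid)))
    cache: dict[int, np.ndarray] = {}
    for i, node in enumerate(nodes):
        key = id(node)
        row = cache.get(key)
        if row is None:
            idx = np.searchsorted(node.times, grid, side="right")
            if survival:
                vals = np.concatenate([[1.0], node.survival])
            else:
                vals = np.concatenate([[0.0], np.cumsum(node.increments)])
            row = vals[idx]
            cache[key] = row
        out[i] = row
    return out


# ----------------------------------------------------------------------
# growth
# ----------------------------------------------------------------------
def _fit_terminal(node: _Node, time, status, entry):
    ev = status == 1
    node.n_rows = len(time)
    node.n_events = int(ev.sum())
    if not ev.any():
        node.times = np.empty(0)
        node.increments = np.empty(0)
        node.survival = np.empty(0)
        return
    ev_times, counts = np.unique(time[ev], return_counts=True)
    risk = _risk_counts(time, entry, ev_times)
    node.times = ev_times
    node.increments = counts / risk
    node.survival = np.cumprod(1.0 - np.clip(node.increments, 0.0, 1.0))


def _grow(
    X: np.ndarray,
    time: np.ndarray,
    status: np.ndarray,
    entry: np.ndarray,
    case_ids: np.ndarray,
    kinds: Sequence[str],
    names: Sequence[str],
    params: GrowthParams,
    rng: np.random.Generator,
) -> _Node:
    def build(idx: np.ndarray) -> _Node:
        node = _Node()
        n_events = int(status[idx].sum())
        splittable = n_events >= 2 * params.min_events
        if params.min_unique > 1 and len(np.unique(case_ids[idx])) < 2 * params.min_unique:
            splittable = False
        best = None
        best_mask = None
        if splittable:
            cands = propose_splits(X[idx], kinds, names, params.K, rng, params.n_cuts)
            best_stat = -1.0
            for cand in cands:
                mask = cand.goes_left(X[idx, cand.index])
                nl = int(mask.sum())
                if nl == 0 or nl == len(idx):
                    continue
                ev_l = int(status[idx][mask].sum())
                ev_r = n_events - ev_l
                if ev_l < params.min_events or ev_r < params.min_events:
                    continue
                if params.min_unique > 1:
                    if (
                        len(np.unique(case_ids[idx][mask])) < params.min_unique
                        or len(np.unique(case_ids[idx][~mask])) < params.min_unique
                    ):
                        continue
                stat = logrank_statistic(time[idx], status[idx], mask, entry[idx])
                if stat > best_stat:  # ties keep the first candidate in proposal order
                    best_stat = stat
                    best = SplitRule(
                        cand.index,
                        cand.name,
                        cand.kind,
                        threshold=cand.threshold,
                        left_categories=cand.left_categories,
                        statistic=stat,
                    )
                    best_mask = mask
        if best is None:
            _fit_terminal(node, time[idx], status[idx], entry[idx])
            return node
        node.split = best
        node.n_rows = len(idx)
        node.n_events = n_events
        node.left = build(idx[best_mask])
        node.right = build(idx[~best_mask])
        return node

    return build(np.arange(len(time)))


def grow_ermt(
    td: TransitionDataset,
    K: int | None = None,
    min_events: int = 6,
    n_cuts: int = 1,
    rng: np.random.Generator | int | None = None,
    encoder: CovariateEncoder | None = None,
) -> MultistateTree:
    """Grow one extremely randomized multistate tree on the full dataset.

    Splitting continues while a candidate can leave at least ``min_events``
    observed events in each daughter; terminals are fitted by Nelson-Aalen.
    A dataset with zero events yields a root-only zero-hazard tree (warned).
    """
    rng = np.random.default_rng(rng)
    if encoder is None:
        encoder = CovariateEncoder(td.categorical).fit(td.covariates)
    X = encoder.transform(td.covariates)
    p = X.shape[1]
    params = GrowthParams(K=default_K(p) if K is None else K, min_events=min_events, n_cuts=n_cuts)
    if td.n_events == 0:
        warnings.warn("transition dataset has zero events; returning a zero-hazard root tree")
    kinds = [encoder.kinds[c] for c in encoder.columns]
    root = _grow(
        X, td.time, td.status, td.entry, np.arange(td.n), kinds, list(encoder.columns), params, rng
    )
    return MultistateTree(td.transition, root, encoder, params)


def grow_bootstrap_tree(
    td: TransitionDataset,
    K: int | None = None,
    n0: int = 6,
    min_events: int = 6,
    n_cuts: int = 1,
    rng: np.random.Generator | int | None = None,
    encoder: CovariateEncoder | None = None,
) -> tuple[MultistateTree, np.ndarray]:
    """Grow a tree on a with-replacement bootstrap; return (tree, OOB indices).

    Stopping additionally requires at least ``n0`` unique original cases per
    terminal, counted on the bootstrap multiset (about 37% of rows fall out
    of bag on average).
    """
    rng = np.random.default_rng(rng)
    if encoder is None:
        encoder = CovariateEncoder(td.categorical).fit(td.covariates)
    n = td.n
    draw = rng.integers(0, n, size=n)
    oob = np.setdiff1d(np.arange(n), draw)
    X = encoder.transform(td.covariates)[draw]
    p = X.shape[1]
    params = GrowthParams(
        K=default_K(p) if K is None else K,
        min_events=min_events,
        min_unique=n0,
        n_cuts=n_cuts,
    )
    if td.status[draw].sum() == 0:
        warnings.warn("bootstrap sample has zero events; returning a zero-hazard root tree")
    kinds = [encoder.kinds[c] for c in encoder.columns]
    root = _grow(
        X,
        td.time[draw],
        td.status[draw],
        td.entry[draw],
        draw,
        kinds,
        list(encoder.columns),
        params,
        rng,
    )
    return MultistateTree(td.transition, root, encoder, params), oob
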