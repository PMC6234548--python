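"""Prediction-performance machinery: IPCW Brier score, C-index, VIMP, holdout harness.

The Brier score for state h at time s is the mean squared difference between
the occupation indicator I{X(s) = h} and the predicted probability. Under
right censoring the residuals are reweighted by the inverse of the censoring
survival G: subjects already past an observed terminal event get weight
1/G(t-), subjects still under observation weight 1/G(s), and subjects
censored before s weight 0; on uncensored data all weights are one and the
two estimators coincide summand by summand.

Variable importance follows the random-daughter scheme: test cases are
dropped down each tree and routed to a uniformly random daughter whenever a
split on the probed covariate is met; VIMP is the increase in integrated
Brier score over the intact ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _lifelines_cindex

from .data import MultistateDataset, TransitionDataset, extract_transition_dataset
from .nonparametric import CensoringSurvival, censoring_survival


@dataclass
class BrierCurve:
    """Pointwise prediction error for one state with its integrated summary."""

    state: int | tuple[int, int]
    grid: np.ndarray
    values: np.ndarray
    integrated: float
    tau_star: float
    n_dropped: int = 0


def integrated_brier(grid: np.ndarray, values: np.ndarray, tau_star: float | None = None) -> float:
    """Trapezoid integral of the Brier curve over [0, tau*], normalized by tau*."""
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if tau_star is None:
        tau_star = float(grid[-1])
    keep = grid <= tau_star
    g, v = grid[keep], values[keep]
    if len(g) < 2 or tau_star <= 0:
        return float(v[0]) if len(v) else 0.0
    return float(np.trapezoid(v, g) / (g[-1] - g[0]))


def default_tau_star(times: np.ndarray, q: float = 0.90) -> float:
    """Default integration horizon: the q-quantile of observed times.

    Avoids the instability of 1/G in the extreme right tail.
    """
    return float(np.quantile(np.asarray(times, dtype=float), q))


def _ipcw_weights(time, status, grid, G: CensoringSurvival, cap: float):
    """Weight matrix (n, len(grid)) per the IPCW decomposition; returns (w, dropped)."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    grid = np.asarray(grid, dtype=float)
    n, k = len(time), len(grid)
    w = np.zeros((n, k))
    G_left = np.asarray(G.left(time), dtype=float)  # G(t_i -)
    G_grid = np.asarray(G(grid), dtype=float)
    past_event = (time[:, None] <= grid[None, :]) & (status[:, None] == 1)
    at_risk = time[:, None] > grid[None, :]
    with np.errstate(divide="ignore"):
        w_event = np.where(G_left > 0, 1.0 / G_left, np.inf)[:, None]
        w_risk = np.where(G_grid > 0, 1.0 / G_grid, np.inf)[None, :]
    w = past_event * w_event + at_risk * w_risk
    dropped = int(np.isinf(w).sum())
    w = np.where(np.isinf(w), 0.0, np.minimum(w, cap))
    return w, dropped


def transition_brier(
    surv_pred: np.ndarray,
    td: TransitionDataset,
    grid: np.ndarray | None = None,
    G: CensoringSurvival | None = None,
    tau_star: float | None = None,
    weight_cap: float = 20.0,
) -> BrierCurve:
    """IPCW Brier curve for one transition's destination-state occupation.

    ``surv_pred`` holds predicted event-free probabilities P(T > s | z) per
    row of ``td`` over ``grid`` (on the transition's clock). Competing exits
    play their separate-approach role of censorings. With no censored rows
    the weights are identically one (the uncensored estimator).
    """
    if grid is None:
        grid = np.unique(td.time[td.status == 1])
    grid = np.asarray(grid, dtype=float)
    surv_pred = np.asarray(surv_pred, dtype=float)
    if surv_pred.shape != (td.n, len(grid)):
        raise ValueError("surv_pred must be (n_rows, len(grid))")
    if tau_star is None:
        tau_star = default_tau_star(td.time)
    if G is None:
        G = censoring_survival(td)
    pi = 1.0 - surv_pred
    occupied = (td.time[:, None] <= grid[None, :]) & (td.status[:, None] == 1)
    resid2 = (occupied.astype(float) - pi) ** 2
    w, dropped = _ipcw_weights(td.time, td.status, grid, G, weight_cap)
    values = (w * resid2).sum(axis=0) / td.n
    return BrierCurve(td.transition, grid, values, integrated_brier(grid, values, tau_star), tau_star, dropped)


def state_occupation_brier(
    pi: np.ndarray,
    test: MultistateDataset,
    state: int,
    grid: np.ndarray,
    G: CensoringSurvival | None = None,
    tau_star: float | None = None,
    weight_cap: float = 20.0,
) -> BrierCurve:
    """Multistate Brier curve for occupation of ``state`` on the study clock.

    ``pi`` holds predicted occupation probabilities per subject (rows aligned
    with ``test.subject_ids``) over ``grid``. ``G`` defaults to the reverse
    Kaplan-Meier of the test subjects' last-contact times; pass ``None`` on
    uncensored data for the plain estimator.
    """
    grid = np.asarray(grid, dtype=float)
    pi = np.asarray(pi, dtype=float)
    summ = test.subject_summary()
    ids = test.subject_ids
    if pi.shape != (len(ids), len(grid)):
        raise ValueError("pi must be (n_subjects, len(grid))")
    t_last = summ.loc[ids, "t_last"].to_numpy()
    absorbed = summ.loc[ids, "absorbed"].to_numpy()
    if tau_star is None:
        tau_star = default_tau_star(t_last)
    if G is None:
        G = censoring_survival(t_last, absorbed.astype(int))
    occupied = np.zeros((len(ids), len(grid)))
    observable = np.zeros((len(ids), len(grid)), dtype=bool)
    for i, sid in enumerate(ids):
        for k, s in enumerate(grid):
            x = test.state_at(sid, float(s))
            occupied[i, k] = 1.0 if x == state else 0.0
            observable[i, k] = x != 0
    resid2 = (occupied - pi) ** 2
    w, dropped = _ipcw_weights(t_last, absorbed.astype(int), grid, G, weight_cap)
    w = w * observable  # the x(s) != 0 indicator of the weight's first term
    values = (w * resid2).sum(axis=0) / len(ids)
    return BrierCurve(state, grid, values, integrated_brier(grid, values, tau_star), tau_star, dropped)


def concordance_index(risk: np.ndarray, time: np.ndarray, status: np.ndarray) -> float:
    """Harrell's C: concordant fraction among pairs orderable under censoring.

    ``risk`` is higher-is-riskier (e.g. ensemble cumulative hazard at a fixed
    horizon); ties in risk count one half. Returns NaN when no pair is usable.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    try:
        # lifelines scores higher-is-longer-lived, hence the negation
        return float(_lifelines_cindex(time, -risk, status))
    except ZeroDivisionError:
        return float("nan")


def ensemble_risk_scores(results, transition, td: TransitionDataset, horizon: float | None = None) -> np.ndarray:
    """Default risk score: ensemble cumulative hazard at the median event time."""
    if horizon is None:
        ev = td.time[td.status == 1]
        horizon = float(np.median(ev)) if len(ev) else float(np.median(td.time))
    return results.predict_cumulative_hazard(transition, td.covariates, [horizon])[:, 0]


# ----------------------------------------------------------------------
# variable importance
# ----------------------------------------------------------------------
def _per_subject_ibs(
    surv: np.ndarray,
    td: TransitionDataset,
    grid: np.ndarray,
    G: CensoringSurvival,
    tau_star: float,
    weight_cap: float = 20.0,
) -> np.ndarray:
    """Per-row integrated weighted squared residual (mean over rows = IBS)."""
    pi = 1.0 - surv
    occupied = (td.time[:, None] <= grid[None, :]) & (td.status[:, None] == 1)
    resid2 = (occupied.astype(float) - pi) ** 2
    w, _ = _ipcw_weights(td.time, td.status, grid, G, weight_cap)
    keep = grid <= tau_star
    g = grid[keep]
    if len(g) < 2:
        return (w * resid2)[:, :1].ravel()
    return np.trapezoid((w * resid2)[:, keep], g, axis=1) / (g[-1] - g[0])


def vimp(
    results,
    test: MultistateDataset,
    covariates: Sequence[str] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    grid_size: int = 50,
) -> pd.DataFrame:
    """Random-daughter VIMP per covariate and transition.

    For each probed covariate x, test rows are dropped down every tree with
    splits on x resolved by a fair coin; VIMP is the increase in integrated
    Brier score over the intact ensemble, averaged over ``n_repeats``
    randomization draws. The reported standard error combines the dominant
    test-set sampling component (VIMP is a mean over subjects of per-subject
    error differences) with the Monte Carlo spread over randomization draws.
    A covariate never used in any split has VIMP exactly 0.

    Returns a tidy frame (covariate, transition, vimp, se, error_intact).
    """
    st = results.structure
    ss = np.random.SeedSequence(seed)
    rows = []
    augment = results.markov_mode == "sojourn_augmented"
    for tr in st.transitions:
        ens = results.ensembles[tr]
        td = extract_transition_dataset(test, tr, augment_sojourn=augment)
        if td.n == 0 or td.n_events == 0:
            continue
        ev_times = np.unique(td.time[td.status == 1])
        grid = ev_times if len(ev_times) <= grid_size else np.quantile(ev_times, np.linspace(0, 1, grid_size))
        tau_star = default_tau_star(td.time)
        G = censoring_survival(td)
        surv0 = ens.predict_survival(td.covariates, grid)
        ps0 = _per_subject_ibs(surv0, td, grid, G, tau_star)
        err0 = float(ps0.mean())
        probe = covariates if covariates is not None else list(td.covariate_names)
        used = ens.split_variables()
        X = ens.encoder.transform(td.covariates)
        for name in probe:
            if name not in td.covariate_names:
                continue
            if name not in used:
                rows.append({"covariate": name, "transition": f"{tr[0]}->{tr[1]}",
                             "vimp": 0.0, "se": 0.0, "error_intact": err0})
                continue
            deltas = []
            for child in ss.spawn(n_repeats):
                rng = np.random.default_rng(child)
                surv = np.zeros_like(surv0)
                for tree in ens.trees:
                    surv += tree.survival_matrix(X, grid, randomize_on={name}, rng=rng)
                surv /= ens.n_trees
                deltas.append(_per_subject_ibs(surv, td, grid, G, tau_star) - ps0)
            D = np.asarray(deltas)  # (repeats, rows)
            per_subject = D.mean(axis=0)
            se_subject = float(per_subject.std(ddof=1) / np.sqrt(td.n)) if td.n > 1 else 0.0
            se_mc = (
                float(D.mean(axis=1).std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0
            )
            rows.append({"covariate": name, "transition": f"{tr[0]}->{tr[1]}",
                         "vimp": float(per_subject.mean()),
                         "se": float(np.hypot(se_subject, se_mc)),
                         "error_intact": err0})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# repeated train/test harness
# ----------------------------------------------------------------------
def repeated_holdout(
    dataset: MultistateDataset,
    models: Mapping[str, Callable[[MultistateDataset], object]],
    n_repeats: int = 10,
    split_fraction: float = 0.67,
    seed: int = 0,
    grid_size: int = 50,
) -> pd.DataFrame:
    """Repeated subject-level train/test evaluation (integrated Brier and C-index).

    ``models`` maps a method name to a factory taking the training dataset and
    returning a fitted results object with ``predict_transition_survival`` and
    ``predict_cumulative_hazard``. Train size is floor(split_fraction * n)
    subjects; all of a subject's records stay on one side. Repeats with zero
    test events for a transition leave that cell missing.

    Returns a tidy frame (method, transition, metric, mean, sd, n_effective).
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    ss = np.random.SeedSequence(seed)
    ids = np.asarray(dataset.subject_ids)
    n_train = int(np.floor(split_fraction * len(ids)))
    cells: dict = {}
    for rep, child in enumerate(ss.spawn(n_repeats)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(ids))
        train = dataset.subset(ids[perm[:n_train]])
        test = dataset.subset(ids[perm[n_train:]])
        for mname, factory in models.items():
            fitted = factory(train)
            augment = getattr(fitted, "markov_mode", "markov") == "sojourn_augmented"
            for tr in dataset.structure.transitions:
                td = extract_transition_dataset(test, tr, augment_sojourn=augment)
                key_ibs = (mname, tr, "ibs")
                key_c = (mname, tr, "cindex")
                cells.setdefault(key_ibs, []).append(np.nan)
                cells.setdefault(key_c, []).append(np.nan)
                if td.n == 0 or td.n_events == 0:
                    continue
                ev_times = np.unique(td.time[td.status == 1])
                grid = ev_times if len(ev_times) <= grid_size else np.quantile(
                    ev_times, np.linspace(0, 1, grid_size)
                )
                surv = fitted.predict_transition_survival(tr, td.covariates, grid)
                bc = transition_brier(surv, td, grid)
                cells[key_ibs][-1] = bc.integrated
                risk = ensemble_risk_scores(fitted, tr, td)
                cells[key_c][-1] = concordance_index(risk, td.time, td.status)
    rows = []
    for (mname, tr, metric), vals in cells.items():
        vals = np.asarray(vals, dtype=float)
        ok = ~np.isnan(vals)
        rows.append(
            {
                "method": mname,
                "transition": f"{tr[0]}->{tr[1]}",
                "metric": metric,
                "mean": float(vals[ok].mean()) if ok.any() else np.nan,
                "sd": float(vals[ok].std(ddof=1)) if ok.sum() > 1 else 0.0,
                "n_effective": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)
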