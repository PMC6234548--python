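"""Brier score (plain and IPCW), concordance, VIMP, repeated holdout."""

import numpy as np
import pandas as pd
import pytest
from sksurv.metrics import concordance_index_censored

from mstforest.data import TransitionDataset
from mstforest.evaluation import (
    concordance_index,
    integrated_brier,
    repeated_holdout,
    state_occupation_brier,
    transition_brier,
    vimp,
)
from mstforest.model import AalenJohansenBaseline, RecursivelyImputedTrees
from mstforest.nonparametric import censoring_survival


def make_td(times, status, cov=None, transition=(1, 2)):
    n = len(times)
    return TransitionDataset(
        transition,
        "forward",
        np.asarray(times, float),
        np.asarray(status, int),
        np.zeros(n),
        np.zeros(n),
        np.zeros(n, bool),
        cov if cov is not None else pd.DataFrame({"x": np.zeros(n)}),
        np.arange(n),
    )


class TestBrier:
    def test_perfect_oracle_zero_error(self):
        td = make_td([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        grid = np.array([0.5, 2.5, 4.5])
        # oracle: survival indicator I{T > s} per subject
        surv = (td.time[:, None] > grid[None, :]).astype(float)
        bc = transition_brier(surv, td, grid)
        assert np.allclose(bc.values, 0.0)
        assert bc.integrated == 0.0

    def test_constant_predictor_hand_value(self):
        # 3 of 5 subjects have reached the destination by s; pi = 0.3
        td = make_td([1, 2, 3, 9, 9.5], [1, 1, 1, 1, 1])
        grid = np.array([5.0])
        surv = np.full((5, 1), 0.7)
        bc = transition_brier(surv, td, grid)
        expected = (3 * (1 - 0.3) ** 2 + 2 * (0 - 0.3) ** 2) / 5
        assert bc.values[0] == pytest.approx(expected, abs=1e-12)

    def test_ipcw_reduces_to_plain_on_uncensored_data(self):
        """Weighted and unweighted summands agree exactly without censoring."""
        rng = np.random.default_rng(0)
        times = rng.exponential(5, 40) + 0.01
        td = make_td(times, np.ones(40, int))
        grid = np.quantile(times, [0.2, 0.5, 0.8])
        surv = rng.random((40, 3))
        ipcw = transition_brier(surv, td, grid, G=censoring_survival(td))
        pi = 1.0 - surv
        occupied = (td.time[:, None] <= grid[None, :]).astype(float)
        plain = ((occupied - pi) ** 2).mean(axis=0)
        assert np.array_equal(ipcw.values, plain)

    def test_trivial_predictor_bound(self):
        """pi = empirical frequency never exceeds 0.25 on uncensored data."""
        rng = np.random.default_rng(7)
        times = rng.exponential(3, 200) + 0.01
        td = make_td(times, np.ones(200, int))
        grid = np.quantile(times, np.linspace(0.05, 0.95, 19))
        freq = (td.time[:, None] <= grid[None, :]).mean(axis=0)
        surv = np.tile(1 - freq, (200, 1))
        bc = transition_brier(surv, td, grid)
        assert np.all(bc.values <= 0.25 + 1e-12)

    def test_censored_subjects_dropped_after_censoring(self):
        # one subject censored at 2: zero weight at s >= 2, reweighting others
        td = make_td([2.0, 3.0, 5.0], [0, 1, 1])
        grid = np.array([4.0])
        surv = np.full((3, 1), 0.5)
        G = censoring_survival(td)
        bc = transition_brier(surv, td, grid, G=G)
        # G(4) = G at censoring jump 2 with risk 3 -> 2/3; weights: 0 (censored),
        # 1/G(3-) = 3/2 for the event at 3, 1/G(4) = 3/2 for the at-risk subject
        expected = (0 + 1.5 * (1 - 0.5) ** 2 + 1.5 * (0 - 0.5) ** 2) / 3
        assert bc.values[0] == pytest.approx(expected, abs=1e-12)

    def test_integrated_brier_constant_curve(self):
        grid = np.linspace(0, 10, 11)
        assert integrated_brier(grid, np.full(11, 0.2), 10.0) == pytest.approx(0.2)

    def test_state_occupation_brier_multistate(self, toy_dataset):
        grid = np.array([1.5, 4.5])
        pi = np.zeros((4, 2))
        bc = state_occupation_brier(pi, toy_dataset, state=2, grid=grid)
        assert bc.values.shape == (2,)
        assert np.all(bc.values >= 0)


class TestConcordance:
    def test_rank_inverse_scores_give_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(-t, t, np.ones(4, int)) == 1.0

    def test_identical_scores_give_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(np.zeros(4), t, np.ones(4, int)) == 0.5

    def test_enumerated_example(self):
        """times (1,2,3,4), scores (10,9,1,2): 5 of 6 usable pairs concordant."""
        c = concordance_index(np.array([10.0, 9, 1, 2]), np.arange(1.0, 5.0), np.ones(4, int))
        assert c == pytest.approx(5 / 6)

    def test_no_usable_pairs_is_nan(self):
        c = concordance_index(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.zeros(2, int))
        assert np.isnan(c)

    def test_negation_sums_to_one_without_ties(self):
        rng = np.random.default_rng(5)
        t = rng.permutation(20).astype(float) + 1
        risk = rng.normal(size=20)
        s = np.ones(20, int)
        assert concordance_index(risk, t, s) + concordance_index(-risk, t, s) == pytest.approx(1.0)

    def test_matches_sksurv_under_censoring(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(5, 50) + 0.01
        s = rng.integers(0, 2, 50).astype(bool)
        s[0] = True
        risk = rng.normal(size=50)
        expected = concordance_index_censored(s, t, risk)[0]
        assert concordance_index(risk, t, s.astype(int)) == pytest.approx(expected, abs=1e-12)


class TestVimp:
    def test_unsplit_covariate_short_circuits_to_zero(self, small_cohort):
        ds, _ = small_cohort
        # constant extra covariate can never be split on
        table = ds.table.copy()
        table["const"] = 1.0
        from mstforest.data import MultistateDataset

        ds2 = MultistateDataset(table, ds.structure, ds.categorical)
        res = RecursivelyImputedTrees(ds2, M=3, n_cycles=1).fit(seed=0)
        rep = vimp(res, ds2, covariates=["const"], n_repeats=2, seed=0)
        assert (rep["vimp"] == 0.0).all()
        assert (rep["se"] == 0.0).all()

    def test_report_covers_all_covariates_and_transitions(self, small_cohort):
        ds, _ = small_cohort
        res = RecursivelyImputedTrees(ds, M=3, n_cycles=1).fit(seed=0)
        rep = vimp(res, ds, n_repeats=2, seed=0)
        assert set(rep["transition"]) == {"1->2", "2->3"}
        assert set(rep[rep.transition == "1->2"]["covariate"]) == set(ds.covariate_names)


class TestRepeatedHoldout:
    def _models(self):
        return {
            "msrist": lambda ds: RecursivelyImputedTrees(ds, M=3, n_cycles=1).fit(seed=0),
            "aalen_johansen": lambda ds: AalenJohansenBaseline(ds).fit(),
        }

    def test_determinism(self, small_cohort):
        ds, _ = small_cohort
        a = repeated_holdout(ds, self._models(), n_repeats=2, seed=3)
        b = repeated_holdout(ds, self._models(), n_repeats=2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_split_arithmetic(self, small_cohort):
        ds, _ = small_cohort
        captured = {}

        def probe(train_ds):
            captured["n_train"] = train_ds.n_subjects
            return AalenJohansenBaseline(train_ds).fit()

        repeated_holdout(ds, {"aj": probe}, n_repeats=1, split_fraction=0.67, seed=0)
        assert captured["n_train"] == int(np.floor(0.67 * ds.n_subjects))

    def test_summary_shape(self, small_cohort):
        ds, _ = small_cohort
        out = repeated_holdout(ds, self._models(), n_repeats=2, seed=1)
        assert set(out.columns) == {"method", "transition", "metric", "mean", "sd", "n_effective"}
        assert len(out) == 2 * 2 * 2  # methods x transitions x metrics
        assert (out["n_effective"] <= 2).all()

    def test_invalid_args(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ValueError):
            repeated_holdout(ds, self._models(), n_repeats=0)
        with pytest.raises(ValueError):
            repeated_holdout(ds, self._models(), split_fraction=1.5)
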