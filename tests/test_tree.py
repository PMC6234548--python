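"""Tree engine: log-rank splitting, growth, bootstrap, drop-down routing."""

import json

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from mstforest.data import TransitionDataset, extract_transition_dataset
from mstforest.nonparametric import nelson_aalen
from mstforest.tree import (
    MultistateTree,
    default_K,
    grow_bootstrap_tree,
    grow_ermt,
    logrank_statistic,
    propose_splits,
)


def make_td(times, status, cov: pd.DataFrame, categorical=(), transition=(1, 2)):
    n = len(times)
    return TransitionDataset(
        transition,
        "forward",
        np.asarray(times, float),
        np.asarray(status, int),
        np.zeros(n),
        np.zeros(n),
        np.zeros(n, bool),
        cov,
        np.arange(n),
        tuple(categorical),
    )


class TestLogrank:
    def test_identical_groups_zero(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], float)
        s = np.array([1, 1, 0, 1] * 2)
        mask = np.array([True] * 4 + [False] * 4)
        assert logrank_statistic(t, s, mask) == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_match_lifelines_oracle(self):
        t = np.array([1, 2, 3, 4, 5, 11, 12, 13, 14, 15], float)
        s = np.ones(10, int)
        mask = t <= 5
        expected = logrank_test(t[mask], t[~mask], s[mask], s[~mask]).test_statistic
        assert logrank_statistic(t, s, mask) == pytest.approx(expected, rel=1e-10)

    def test_random_data_matches_lifelines(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 60).round(2) + 0.01
        s = rng.integers(0, 2, 60)
        mask = rng.random(60) < 0.5
        expected = logrank_test(t[mask], t[~mask], s[mask], s[~mask]).test_statistic
        assert logrank_statistic(t, s, mask) == pytest.approx(expected, rel=1e-9)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 30)
        s = rng.integers(0, 2, 30)
        mask = rng.random(30) < 0.4
        assert logrank_statistic(t, s, mask) == pytest.approx(
            logrank_statistic(t, s, ~mask), rel=1e-12
        )

    def test_no_events_zero_not_error(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        s = np.zeros(4, int)
        assert logrank_statistic(t, s, np.array([True, True, False, False])) == 0.0

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            logrank_statistic(np.array([1.0]), np.array([1]), np.array([True]))


class TestProposeSplits:
    def test_default_K_is_root_p(self):
        assert default_K(10) == 3
        assert default_K(1) == 1

    def test_constant_covariates_give_empty_list(self):
        X = np.ones((20, 3))
        out = propose_splits(X, ["numeric"] * 3, ["a", "b", "c"], 3, np.random.default_rng(0))
        assert out == []

    def test_seeded_determinism(self):
        X = np.random.default_rng(1).normal(size=(30, 5))
        kinds = ["numeric"] * 5
        names = list("abcde")
        a = propose_splits(X, kinds, names, 3, np.random.default_rng(7))
        b = propose_splits(X, kinds, names, 3, np.random.default_rng(7))
        assert a == b

    def test_categorical_proper_subset(self):
        X = np.repeat([[0.0], [1.0], [2.0]], 10, axis=0)
        out = propose_splits(X, ["categorical"], ["band"], 1, np.random.default_rng(2))
        assert len(out) == 1
        left = out[0].left_categories
        assert 0 < len(left) < 3

    def test_K_cannot_exceed_p(self):
        with pytest.raises(ValueError):
            propose_splits(np.ones((5, 2)), ["numeric"] * 2, ["a", "b"], 3, np.random.default_rng(0))


class TestGrowth:
    def test_root_only_when_nmin_large(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"x": rng.normal(size=30)})
        td = make_td(rng.exponential(5, 30) + 0.01, np.ones(30, int), cov)
        tree = grow_ermt(td, min_events=1000, rng=1)
        assert tree.root.is_terminal
        ch = nelson_aalen(td)
        assert tree.root.times.tolist() == ch.times.tolist()
        assert tree.root.increments.tolist() == ch.increments.tolist()

    def test_perfect_separator_chosen_first(self):
        # binary covariate exactly separating early from late events, K = p = 1
        times = np.concatenate([np.linspace(1, 2, 20), np.linspace(10, 11, 20)])
        cov = pd.DataFrame({"x": np.repeat([0, 1], 20)})
        td = make_td(times, np.ones(40, int), cov)
        tree = grow_ermt(td, K=1, min_events=6, rng=0)
        assert tree.root.split.name == "x"

    def test_terminal_partition_property(self, small_cohort):
        """Terminal rows and events partition the root's rows and events."""
        ds, _ = small_cohort
        td = extract_transition_dataset(ds, (1, 2))
        tree = grow_ermt(td, rng=5)
        terms = tree.terminals()
        assert sum(t.n_rows for t in terms) == td.n
        assert sum(t.n_events for t in terms) == td.n_events

    def test_monotone_stopping(self, small_cohort):
        ds, _ = small_cohort
        td = extract_transition_dataset(ds, (1, 2))
        depths = [grow_ermt(td, min_events=m, rng=9).depth() for m in (4, 8, 16, 64)]
        assert depths == sorted(depths, reverse=True)

    def test_zero_events_warns_root_only(self):
        cov = pd.DataFrame({"x": np.arange(5.0)})
        td = make_td(np.arange(1.0, 6.0), np.zeros(5, int), cov)
        with pytest.warns(UserWarning, match="zero events"):
            tree = grow_ermt(td, rng=0)
        assert tree.root.is_terminal
        assert len(tree.root.times) == 0

    def test_serialization_roundtrip(self, small_cohort):
        ds, _ = small_cohort
        td = extract_transition_dataset(ds, (1, 2))
        tree = grow_ermt(td, rng=3)
        blob = json.dumps(tree.to_dict(), sort_keys=True)
        back = MultistateTree.from_dict(json.loads(blob))
        assert json.dumps(back.to_dict(), sort_keys=True) == blob
        X = tree.encoder.transform(td.covariates)
        grid = np.linspace(0, 10, 7)
        assert np.array_equal(tree.chf_matrix(X, grid), back.chf_matrix(X, grid))


class TestBootstrap:
    def test_same_seed_identical_tree(self, small_cohort):
        ds, _ = small_cohort
        td = extract_transition_dataset(ds, (1, 2))
        t1, o1 = grow_bootstrap_tree(td, rng=np.random.default_rng(11))
        t2, o2 = grow_bootstrap_tree(td, rng=np.random.default_rng(11))
        assert json.dumps(t1.to_dict(), sort_keys=True) == json.dumps(t2.to_dict(), sort_keys=True)
        assert np.array_equal(o1, o2)

    def test_oob_fraction_near_37_percent(self, small_cohort):
        ds, _ = small_cohort
        td = extract_transition_dataset(ds, (1, 2))
        fracs = []
        for seed in range(30):
            _, oob = grow_bootstrap_tree(td, min_events=10_000, rng=np.random.default_rng(seed))
            fracs.append(len(oob) / td.n)
        assert 0.33 < np.mean(fracs) < 0.41

    def test_oob_complements_in_bag(self, small_cohort):
        ds, _ = small_cohort
        td = extract_transition_dataset(ds, (1, 2))
        rng = np.random.default_rng(21)
        draw = rng.integers(0, td.n, td.n)
        _, oob = grow_bootstrap_tree(td, min_events=10_000, rng=np.random.default_rng(21))
        assert np.array_equal(np.sort(np.concatenate([np.unique(draw), oob])), np.arange(td.n))


class TestDropDown:
    def _single_split_tree(self):
        times = np.concatenate([np.linspace(1, 2, 20), np.linspace(10, 11, 20)])
        cov = pd.DataFrame({"x": np.repeat([0.0, 1.0], 20)})
        td = make_td(times, np.ones(40, int), cov)
        return grow_ermt(td, K=1, min_events=6, rng=0)

    def test_root_only_returns_root_payload(self):
        cov = pd.DataFrame({"x": np.zeros(10)})
        td = make_td(np.arange(1.0, 11.0), np.ones(10, int), cov)
        tree = grow_ermt(td, min_events=100, rng=0)
        ch, _ = tree.drop_down({"x": 123.0})
        assert ch.cumulative(10.0) == pytest.approx(nelson_aalen(td).cumulative(10.0))

    def test_routing_by_threshold(self):
        tree = self._single_split_tree()
        lo, _ = tree.drop_down({"x": 0.0})
        hi, _ = tree.drop_down({"x": 1.0})
        # low-x cases are the early-event group: larger early cumulative hazard
        assert lo.cumulative(3.0) > hi.cumulative(3.0)

    def test_missing_split_variable_rejected(self):
        tree = self._single_split_tree()
        with pytest.raises(KeyError):
            tree.drop_down({"y": 1.0})

    def test_randomized_routing_is_fair_coin(self):
        tree = self._single_split_tree()
        X = tree.encoder.transform(pd.DataFrame({"x": np.zeros(10_000)}))
        rng = np.random.default_rng(123)
        nodes = tree.assign_terminals(X, randomize_on={"x"}, rng=rng)
        left = tree.root.left
        frac = np.mean([n is left for n in nodes])
        assert abs(frac - 0.5) < 0.02

    def test_unseen_category_routes_right_and_tallies(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"band": np.repeat(["a", "b"], 20)})
        times = np.concatenate([np.linspace(1, 2, 20), np.linspace(10, 11, 20)])
        td = make_td(times, np.ones(40, int), cov, categorical=("band",))
        tree = grow_ermt(td, K=1, min_events=6, rng=1)
        assert tree.root.split.kind == "categorical"
        X = tree.encoder.transform(pd.DataFrame({"band": ["zzz"]}))
        node = tree.assign_terminals(X)[0]
        assert node is tree.root.right
        assert tree.diagnostics["unseen_category_routed"] == 1
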