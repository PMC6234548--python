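"""Forests, conditional survival, one-step imputation, recursively imputed trees."""

import json

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from mstforest.data import TransitionDataset, extract_transition_dataset
from mstforest.ensemble import (
    PROV_COMPETING,
    PROV_IMPUTED_EVENT,
    PROV_IMPUTED_TAU,
    PROV_ORIGINAL,
    ConditionalLaw,
    TransitionEnsemble,
    conditional_survival,
    fit_msrist,
    fit_msrsf,
    impute_one_step,
)
from mstforest.nonparametric import nelson_aalen


def make_td(times, status, cov=None, competing=None, transition=(1, 2)):
    n = len(times)
    return TransitionDataset(
        transition,
        "forward",
        np.asarray(times, float),
        np.asarray(status, int),
        np.zeros(n),
        np.zeros(n),
        np.zeros(n, bool) if competing is None else np.asarray(competing, bool),
        cov if cov is not None else pd.DataFrame({"x": np.zeros(n)}),
        np.arange(n),
    )


@pytest.fixture(scope="module")
def censored_td(small_cohort):
    ds, _ = small_cohort
    return extract_transition_dataset(ds, (1, 2))


class TestMSRSF:
    def test_single_root_tree_equals_bootstrap_nelson_aalen(self, censored_td):
        td = censored_td
        ens = fit_msrsf(td, B=1, min_events=10**6, seed=0)
        # replicate the bootstrap draw from the same seed path
        child = np.random.SeedSequence(0).spawn(1)[0]
        rng = np.random.default_rng(child)
        draw = rng.integers(0, td.n, td.n)
        expected = nelson_aalen(td.take(draw))
        grid = np.linspace(0.1, td.tau, 23)
        got = ens.predict_cumhaz(td.covariates.iloc[:1], grid)[0]
        assert np.allclose(got, expected.cumulative(grid))

    def test_ensemble_chf_nondecreasing(self, censored_td):
        ens = fit_msrsf(censored_td, B=5, seed=3)
        grid = np.linspace(0, censored_td.tau, 40)
        vals = ens.predict_cumhaz(censored_td.covariates.iloc[:4], grid)
        assert np.all(np.diff(vals, axis=1) >= -1e-12)

    def test_invalid_B_rejected(self, censored_td):
        with pytest.raises(ValueError):
            fit_msrsf(censored_td, B=0)


class TestConditionalSurvival:
    def test_no_events_after_c_all_mass_at_tau(self):
        td = make_td([1, 2, 3, 10], [1, 1, 1, 0])
        ens = fit_msrist(td, M=1, nmin=10**6, n_cycles=1, seed=0)
        law = conditional_survival(ens, {"x": 0.0}, c=5.0)
        assert law.probs.sum() == pytest.approx(0.0)
        assert law.p_tau == pytest.approx(1.0)

    def test_root_only_tree_matches_km_conditional_oracle(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(5, 40).round(2) + 0.05
        status = (rng.random(40) < 0.7).astype(int)
        status[np.argmax(times)] = 1  # keep tau an event so S has support there
        td = make_td(times, status)
        ens = fit_msrist(td, M=1, nmin=10**6, n_cycles=1, seed=0)
        c = float(np.quantile(times, 0.3))
        law = conditional_survival(ens, {"x": 0.0}, c=c)
        km = KaplanMeierFitter().fit(times, status)
        S = lambda t: float(km.survival_function_at_times(t).iloc[0])
        ev = np.unique(times[status == 1])
        ev = ev[ev > c]
        Sc = S(c)
        prev = c
        for t_k, p_k in zip(law.times, law.probs):
            if p_k == 0:
                continue
            assert t_k in ev
            expected = (S(prev) - S(t_k)) / Sc
            assert p_k == pytest.approx(expected, abs=1e-10)
            prev = t_k
        assert law.p_tau == pytest.approx(S(td.tau) / Sc, abs=1e-10)

    def test_c_at_or_beyond_tau_rejected(self):
        td = make_td([1, 2, 3], [1, 1, 1])
        ens = fit_msrist(td, M=1, nmin=10, n_cycles=1, seed=0)
        with pytest.raises(ValueError):
            conditional_survival(ens, {"x": 0.0}, c=3.0)


class TestImputation:
    def test_fully_observed_is_noop(self):
        td = make_td([1, 2, 3, 4], [1, 1, 1, 1])
        ens = fit_msrist(td, M=2, nmin=100, n_cycles=1, seed=0)
        imp = impute_one_step(td, ens, rng=0)
        assert np.array_equal(imp.dataset.time, td.time)
        assert np.array_equal(imp.dataset.status, td.status)
        assert all(p == PROV_ORIGINAL for p in imp.provenance)

    def test_multinomial_frequencies(self):
        """Draws follow the conditional law {t1: 0.3, t2: 0.5, tau-censor: 0.2}."""
        td = make_td([1.0, 9.9, 10.0], [0, 1, 1])  # row 0 censored at 1, tau = 10
        law = ConditionalLaw(np.array([3.0, 6.0]), np.array([0.3, 0.5]), 0.2)
        rng = np.random.default_rng(99)
        counts = {3.0: 0, 6.0: 0, "tau": 0}
        n_draws = 10_000
        for _ in range(n_draws):
            imp = impute_one_step(td, ensemble=None, rng=rng, laws=[law])
            if imp.dataset.status[0] == 1:
                counts[float(imp.dataset.time[0])] += 1
            else:
                assert imp.dataset.time[0] == 10.0
                counts["tau"] += 1
        assert counts[3.0] / n_draws == pytest.approx(0.3, abs=0.02)
        assert counts[6.0] / n_draws == pytest.approx(0.5, abs=0.02)
        assert counts["tau"] / n_draws == pytest.approx(0.2, abs=0.02)

    def test_imputed_events_exceed_censoring_time(self, censored_td):
        td = censored_td
        ens = fit_msrist(td, M=3, n_cycles=1, seed=1)
        imp = impute_one_step(td, ens, rng=5)
        was_cens = (td.status == 0) & ~td.competing
        now_event = imp.dataset.status == 1
        idx = np.nonzero(was_cens & now_event)[0]
        assert len(idx) > 0
        assert np.all(imp.dataset.time[idx] > td.time[idx])

    def test_provenance_partition(self, censored_td):
        td = censored_td
        ens = fit_msrist(td, M=3, n_cycles=1, seed=1)
        imp = impute_one_step(td, ens, rng=2)
        c = imp.counts()
        total = sum(
            c.get(k, 0)
            for k in (PROV_ORIGINAL, PROV_IMPUTED_EVENT, PROV_IMPUTED_TAU, PROV_COMPETING)
        )
        assert total == td.n
        assert c.get(PROV_COMPETING, 0) == int(td.competing.sum())

    def test_competing_exits_never_imputed(self):
        td = make_td([1, 2, 3, 4], [0, 1, 1, 0], competing=[True, False, False, False])
        ens = fit_msrist(td, M=2, nmin=100, n_cycles=1, seed=0)
        imp = impute_one_step(td, ens, rng=3)
        assert imp.dataset.status[0] == 0
        assert imp.dataset.time[0] == 1.0
        assert imp.provenance[0] == PROV_COMPETING


class TestMSRIST:
    def test_degenerate_chain_equals_raw_nelson_aalen(self, censored_td):
        """n_cycles=1, M=1, nmin >= n reproduces the raw Nelson-Aalen exactly."""
        td = censored_td
        ens = fit_msrist(td, M=1, nmin=td.n + 1, n_cycles=1, seed=0)
        expected = nelson_aalen(td)
        grid = np.linspace(0.1, td.tau, 31)
        got = ens.predict_cumhaz(td.covariates.iloc[:1], grid)[0]
        assert np.allclose(got, expected.cumulative(grid), atol=0)

    def test_fully_observed_cycles_are_noop(self):
        rng = np.random.default_rng(2)
        cov = pd.DataFrame({"x": rng.normal(size=50)})
        td = make_td(rng.exponential(4, 50) + 0.01, np.ones(50, int), cov)
        a = fit_msrist(td, M=3, n_cycles=1, seed=7)
        b = fit_msrist(td, M=3, n_cycles=4, seed=7)
        assert json.dumps([t.to_dict() for t in a.trees], sort_keys=True) == json.dumps(
            [t.to_dict() for t in b.trees], sort_keys=True
        )

    def test_seed_determinism_bitwise(self, censored_td):
        a = fit_msrist(censored_td, M=3, n_cycles=2, seed=11)
        b = fit_msrist(censored_td, M=3, n_cycles=2, seed=11)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(b.to_dict(), sort_keys=True)

    def test_invalid_params_rejected(self, censored_td):
        with pytest.raises(ValueError):
            fit_msrist(censored_td, M=0)
        with pytest.raises(ValueError):
            fit_msrist(censored_td, n_cycles=0)

    def test_serialization_roundtrip(self, censored_td):
        ens = fit_msrist(censored_td, M=2, n_cycles=2, seed=4)
        blob = json.dumps(ens.to_dict(), sort_keys=True)
        back = TransitionEnsemble.from_dict(json.loads(blob))
        assert json.dumps(back.to_dict(), sort_keys=True) == blob
        grid = np.linspace(0.5, censored_td.tau, 9)
        Z = censored_td.covariates.iloc[:3]
        assert np.array_equal(ens.predict_survival(Z, grid), back.predict_survival(Z, grid))
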