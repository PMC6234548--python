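# mstforest

Nonparametric tree ensembles for **multistate time-to-event data**:
multistate random survival forests (MSRSF) and multistate recursively
imputed survival trees (MSRIST), for progressive and illness-death
processes such as HIV → AIDS → death.

## The problem

Follow-up studies with intermediate events are naturally described by a
multistate process `X(t)` on a finite state space `S = {1, …, N}`, fully
characterised by its transition intensities

```
α_hj(t) = lim_{Δt→0} P( X(t+Δt) = j | X(t) = h ) / Δt
```

or equivalently its transition probabilities `P_hj(s, t) = P(X(t) = j |
X(s) = h)`. Classical per-transition Cox regression imposes
proportional hazards and linear covariate effects and struggles with
interactions and correlated predictors. This package instead models each
transition's hazard on its own risk set (the *separate approach*) with
tree ensembles:

- **MSRSF** — per transition, `B` bootstrap trees split by the two-sample
  log-rank statistic among `K = ⌊√p⌋` randomly drawn candidate covariates;
  terminal nodes carry Nelson–Aalen estimates `Â_hj` which are averaged
  over trees.
- **MSRIST** — per transition, `M` extremely randomized trees fitted to the
  *full* training data; every censored observation is then replaced by a
  draw from its ensemble-conditional failure law (an event before the
  horizon τ, or censoring at τ), one tree is refitted per imputed dataset,
  and the cycle repeats. Imputation recovers information in censored rows
  and allows deeper trees.

Per-transition ensemble hazards are assembled into the full
transition-probability matrix through the Aalen–Johansen product integral

```
P̂(s, t) = ∏_{u ∈ (s, t]} ( I + dÂ(u) ).
```

Prediction accuracy is measured by the (inverse-probability-of-censoring
weighted) Brier score and Harrell's concordance index; covariates are
ranked by random-daughter variable importance (VIMP): test cases are
routed to a uniformly random daughter whenever a split on the probed
covariate is met, and VIMP is the resulting increase in integrated Brier
score. Applied to the entry time `d` into an intermediate state, the same
machinery yields a practical check of the Markov assumption: a large
sojourn-time VIMP indicates a semi-Markov mechanism.

Because registry data of this kind are rarely shareable, the package ships
a simulator (`mstforest.simulate`) that generates progressive and
illness-death cohorts with known covariate-dependent intensities, Markov
and semi-Markov variants, and independent right censoring — every
estimator is testable against closed-form or Monte Carlo ground truth.

## Worked example

```python
from mstforest import RecursivelyImputedTrees, simulate_cohort, vimp
from mstforest.simulate import hivlike_scenario

cohort, truth = simulate_cohort(hivlike_scenario(500), seed=7)
results = RecursivelyImputedTrees(cohort, M=10, n_cycles=3).fit(seed=7)
print(results.summary())
```

```
                    RecursivelyImputedTrees results
========================================================================
method: msrist    markov_mode: markov    seed: 7
states: (1, 2, 3)    transitions: ((1, 2), (2, 3))
------------------------------------------------------------------------
transition   clock  trees  K  mean_terminals  tau
      1->2 forward     10  3            30.6 10.0
      2->3 forward     10  3             6.9 10.0
========================================================================
```

State-occupation probabilities five years after diagnosis for a treated
34-year-old, at a healthy (+1 SD) versus depleted (−1.5 SD) immune-marker
score:

```python
profile = {"sex": 1, "prison": 0, "smoker": 0, "drug": 0, "tb": 0, "art": 1,
           "cd4_band": "mid", "age": 34.0, "cd4": 1.0, "bmi": 24.0}
results.predict_transition_probabilities(profile, s=0.0, t=5.0)
```

```
P(state at year 5 | healthy marker):  [0.714, 0.253, 0.033]
P(state at year 5 | depleted marker): [0.496, 0.449, 0.055]
```

Each vector is `(P_11, P_12, P_13)` — still infection-only, progressed,
dead — and sums to one; the depleted-marker profile nearly doubles the
five-year progression probability, matching the simulated mechanism
(log-hazard −1.0 per SD of the marker). Variable importance recovers the
planted signal:

```python
report = vimp(results, cohort, n_repeats=5, seed=7)
report[report.transition == "1->2"].nlargest(3, "vimp")
```

```
covariate     vimp       se
      cd4 0.042220 0.003762
      age 0.011267 0.001290
      art 0.010069 0.001735
```

The three covariates that truly drive progression in the simulator (the
immune marker, age, treatment) head the ranking; all others sit within
two standard errors of zero.

A command-line pipeline wraps the same functionality:

```bash
mstforest simulate --n 500 --seed 7 --out cohort.csv
mstforest fit --data cohort.csv --method msrist --seed 7 --out model.json
mstforest evaluate --data cohort.csv --out metrics.csv
```

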