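# Methods

This note documents the models, estimators and numerical choices behind
`mstforest`, the defaults and why they were chosen, what the synthetic
cohorts do and do not emulate, and the known limitations.

## Data model

Event histories are long-format tables: one row per subject-sojourn with
`id, from, to, entry, exit, status` and covariates. Censoring is encoded
as an exit to state 0 with status 0, which doubles as the observability
convention: a subject's state path `x(s)` is reconstructible by
piecewise-constant interpolation while under observation and reported as
unknown (0) after a censored last contact; subjects observed to enter an
absorbing state remain there forever. Times are continuous nonnegative
reals on a per-subject study clock starting at entry into the initial
state; calendar dates must be converted upstream. Within-subject ties
(zero-length sojourns) are rejected; between-subject ties are allowed and
handled by all estimators. Recurrent visits to a state, interval
censoring and left truncation other than state-entry times are out of
scope.

Each transition (h, j) is analysed on its own risk set (the separate
approach): all subjects ever in h, with exits to other destinations
treated as cause-specific censorings and flagged `competing`. Two clocks
are supported per transition: *forward* (study time; rows out of
non-initial states are left-truncated at their state-entry time d) and
*reset* (sojourn time; truncation is zero). A reset clock on transitions
out of the initial state is rejected as redundant. Sojourn augmentation
optionally injects d as a covariate (`entry_time`) for transitions out of
non-initial states — the handle used by the semi-Markov analysis. The
complementary t − d is the reset-clock outcome time itself and is not
additionally injected by default.

## Nonparametric estimators

- **Nelson–Aalen** per transition: jumps ΔN_hj(u)/Y_h(u) at observed
  event times, with Y counting rows whose truncation entry < u ≤ time.
  Terminal nodes of trees use the same estimator on their rows, so a
  root-only tree reproduces it exactly (a tested identity).
- **Aalen–Johansen**: the product integral over pooled jump times, each
  factor I + dÂ(u) with off-diagonal (h, j) entry ΔÂ_hj(u) and a
  compensating diagonal. Factors are applied at event times only
  (censoring enters through risk sets); a factor whose total outgoing
  increment exceeds one is rejected with the offending time point. Rows
  sum to one by construction and Chapman–Kolmogorov holds exactly at
  pooled jump times. Variance estimation is not provided.
- **Markov illness-death closed forms**: P11(s,t) = exp(−(A12+A13)),
  P22 = exp(−A23), P12 = ∫ P11(s,u) α12(u) P22(u,t) du by adaptive
  quadrature (absolute tolerance 1e−8), P13 by conservation. Used as the
  ground-truth oracle for simulated Markov scenarios.
- **Censoring survival Ĝ** for IPCW: Kaplan–Meier with the roles of
  event and censoring reversed, with exact left limits Ĝ(t−). Ĝ is
  estimated marginally (unconditional on covariates); a user-supplied
  conditional estimator can be passed wherever a `CensoringSurvival` is
  accepted. No tie-order adjustment is applied at shared event/censoring
  times.

## Trees and ensembles

Splitting is extremely randomized: at each node, K candidate covariates
are drawn without replacement (default K = ⌊√p⌋); each numeric candidate
receives `n_cuts` uniform random cut points in the open observed range
(default 1), each categorical candidate a uniformly random nonempty
proper subset of its observed levels. The winner maximizes the
two-sample log-rank chi-square (tie-corrected hypergeometric variance,
left-truncation-aware); ties keep the first candidate in proposal order,
so growth is reproducible given the seed. A node is terminal when no
candidate can leave at least `min_events` (default 6) of this
transition's events in both daughters — checked pre-emptively via the
2·min_events bound — or, for bootstrap trees, at least `n0` (default 6)
unique original cases. Splits with zero statistic are still accepted;
the event constraint bounds depth. Categorical levels unseen at
prediction time are routed to the right daughter and tallied in the
tree's diagnostics.

**MSRSF** grows B (default 1000) trees on with-replacement bootstrap
samples and records out-of-bag indices. **MSRIST** runs `n_cycles`
(default 5) fitting cycles of M (default 50) trees: the first on the raw
data, each later cycle refitting one tree per independently imputed
dataset. Imputation draws each imputable censored row's outcome from the
ensemble-conditional law on the pooled jump grid restricted to (c, τ]:
an event at a grid time with probability (S(t_{k−1}) − S(t_k))/S(c), or
censoring at τ with the residual mass, where τ is the largest observed
time on the transition's clock and S the tree-averaged product-limit
survival. Rows censored by a competing exit are never imputed — their
time to this transition is structurally unobservable, and fabricating
latent competing failure times would inject counterfactuals. If
S(c) = 0 the conditional law is degenerate and the row is imputed at the
first grid time after c (flagged). On fully observed data the cycles are
skipped: they would refit the same empirical law. Only the final cycle's
trees form the ensemble; earlier cycles are discarded.

All fitting is driven by `numpy.random.SeedSequence` spawning (one child
per transition, per cycle, per tree), so results are independent of
execution order and byte-identical under a repeated seed — model bundles
serialize to sorted-key JSON and are compared bytewise in the tests.

## Multistate prediction

`predict_transition_probabilities(z, s, t, current_state, entry_offset)`
evaluates each transition's ensemble cumulative hazard for z on its own
clock, maps jumps to the study clock, and assembles the product integral
over the pooled grid in (s, t]. Reset clocks out of the current state are
shifted by the supplied entry time d; reset clocks out of *downstream*
states are approximated by restarting their clock at s (their true entry
times are future random quantities; no product-integral representation
exists for genuine semi-Markov probabilities). Under sojourn
augmentation, d is injected into z for transitions out of the current
state. For Markov (all-forward-clock) structures the assembly is exact
in the Aalen–Johansen sense, and with root-only trees it reproduces the
covariate-free estimator bitwise.

## Evaluation

The per-transition Brier curve at time s is the mean weighted squared
difference between the destination-occupation indicator and the
predicted probability 1 − Ŝ(s|z). IPCW weights: rows with an observed
event by s get 1/Ĝ(T−), rows still at risk get 1/Ĝ(s), rows censored by
s get 0; on uncensored data all weights are one and the weighted and
plain estimators agree summand by summand (asserted exactly). Weights
are capped at 20 and terms with Ĝ = 0 dropped with a count. The
integrated Brier score uses the trapezoid rule over [0, τ*], normalized
by the range, with τ* defaulting to the 90th percentile of observed
times to avoid tail instability of 1/Ĝ. A state-occupation variant on
the study clock implements the same weighting for the full multistate
path using per-subject last-contact times.

The concordance index is Harrell's (pairs orderable under censoring;
score ties count one half; undefined — NaN, not 0.5 — without usable
pairs), computed through lifelines and cross-checked against
scikit-survival in the tests. The default risk score is the ensemble
cumulative hazard at the median event time.

VIMP follows the random-daughter scheme: test rows are dropped down every
tree with splits on the probed covariate resolved by a fair coin; VIMP is
the increase in integrated Brier score, averaged over `n_repeats`
(default 10) randomization draws, computed per transition. A covariate
absent from every split short-circuits to exactly zero. The reported
standard error combines the test-set sampling component (the standard
error over subjects of the per-subject error difference — the dominant
uncertainty of a mean-over-subjects estimator) with the Monte Carlo
spread over randomization draws. Note the scheme has a small positive
noise floor (random 50/50 routing replaces routing by the empirical
split proportions), which the subject-level SE correctly dominates on
held-out data.

`repeated_holdout` draws seeded subject-level splits (default train
fraction 0.67, floor rule; all records of a subject stay together), fits
each configured model on the training part and reports mean (sd) of IBS
and C-index per transition; repeats with zero test events leave a
missing cell that is counted, not imputed.

## Synthetic cohorts

The simulator draws, per occupied state, competing transition times by
exact inverse transform on cumulative hazards α_hj(t)·exp(β′z)
(exponential or Weibull baselines, on the transition's declared clock;
forward-clock draws are conditioned on T > d analytically), takes the
minimum, and applies independent right censoring (exponential
loss-to-follow-up and/or an administrative horizon). Covariates, event
times and censoring use independent seed substreams, so the latent
uncensored path — returned alongside the observed records — is invariant
to the censoring configuration. Competing times are generated as
independent latent clocks, which is observationally equivalent to any
mechanism with the same intensities. A semi-Markov mechanism multiplies
a reset-clock hazard by exp(γ·(d − center)).

The default `hivlike` scenario is a ten-year progressive cohort of 2473
subjects with ten covariates (six binary, one three-level categorical,
three continuous), three of which carry signal: a standardized immune
marker (log-hazard −1.0 per SD on progression, −0.3 on death), treatment
(−0.5, −0.8) and age (+0.02 per year on progression). Baseline rates
0.06 and 0.055 per year with exponential censoring at rate 0.055 under a
10-year horizon were calibrated once so that roughly half the cohort
progresses and roughly a quarter of progressors die — the shape of a
typical registry cohort of this size. The matched Markov/semi-Markov
pair for the sojourn-VIMP check shares all rates and covariate effects
and differs only in γ (0 vs 0.6 around a 2-year center) on the reset
2 → 3 sojourn hazard; with an exponential baseline the γ = 0 member is
Markov in law.

What the simulator does not emulate: correlated covariates, a joint
covariate distribution calibrated to any real registry,
covariate-dependent or informative censoring, measurement error,
recurrent states, and time-varying covariates. Passing tests therefore
demonstrate correctness of the estimators and the method's behavior
under its own assumptions, not performance on real registry data.

## Problem sizes in the checked examples

The test suite and the acceptance script run at deliberately modest
sizes chosen to exercise every code path while keeping the whole suite
fast on a single CPU: ensembles of M = 10 trees over 3 cycles (or
B = 50–100 bootstrap trees) on cohorts of 300–800 subjects for
model-level checks, n = 2000 for estimator-consistency checks, and 10–20
replicates for stochastic claims. The paper-scale defaults (B = 1000,
M = 50, five cycles) remain the package defaults.

## Known limitations

- Semi-Markov transition probabilities are approximated (see above);
  only per-transition quantities are exact under reset clocks.
- Ĝ is marginal; strongly covariate-dependent censoring biases the IPCW
  Brier score.
- The random-daughter VIMP has a positive noise floor on variables used
  in splits; compare against its reported SE, not against zero.
- Trees handle categorical covariates by random level subsets; with very
  high-cardinality factors the subset draw explores the split space
  slowly.
- The C-index under censoring uses Harrell's pair-eligibility convention;
  alternatives (e.g. IPCW-weighted C) are not implemented.
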