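# Methods

## Association networks

Scan samples record a partition of each group into parties (party
co-membership stands in for the field rule "within one body length";
parties are its transitive closure, so the file format carries parties,
not pairwise distances). The simple ratio index for dyad (i, j) is the
number of scans they shared a party divided by the number of scans in
which both were present. Dyads never co-present get index 0 with a logged
warning rather than a missing value, so downstream matrices are complete.
Networks are immutable snapshots tagged with a round label; rosters may
differ between rounds (animals die, leave or return), and each diffusion
is linked to the network in force for its (group, round).

The social differentiation coefficient is sd/mean of the dyadic indices.
The sample (n-1) standard deviation is the default; a flag switches to the
population form, since observational practice varies and the quantity is a
descriptive diagnostic either way.

The Mantel comparison between two networks restricts to shared
individuals, correlates the off-diagonal dyad vectors (Pearson), and draws
its p-value from simultaneous row/column label permutations with the +1
correction, one-sided (greater) — the common default in ecological
permutation software. The seed is mandatory; results are reproducible.

## The TADA likelihood

Acquisition is modelled as a continuous-time hazard
`lambda_i(t) = lambda0(t) R_i(t)` for each naive individual, with
`R_i` as in the README table and `T_i = sum_j a_ij z_j`. Because the
informed set changes only at acquisition events, `R_i` is piecewise
constant, and each diffusion contributes

```
sum_events [log lambda0(t_e) + log R_{i_e}(t_e-)]
  - sum_i sum_intervals R_i * [Lambda0(t_hi) - Lambda0(t_lo)]
```

with censored individuals integrating to the trial end. Baseline and ILV
coefficients are shared across all diffusions and groups within one fit
(one round, one behaviour); `s` is shared across groups and split by task
type only under the "different" constraint. Innovators need no special
casing: `T_i = 0` at their event makes the social component vanish; the
"excluding the innovator" rule enters only the %ST denominator.

"Additive" is implemented literally as ILVs affecting the asocial term
only (no separate social-ILV coefficient vector). The broader NBDA
framework allows ILVs on the social term too; that extension is
deliberately excluded from the replication model space to keep the
additive/multiplicative contrast interpretable as
independent-versus-interacting learning processes.

### Baselines and numerical choices

The constant baseline has `Lambda0(t) = lambda0 t`. The gamma baseline is
the hazard of a Gamma(shape, rate) distribution, evaluated via the
log-survival function so large times never produce NaN; where the
log-survival underflows even in log space the hazard is continued with its
asymptote (`sf ~ pdf / rate`, hazard -> rate). Gamma(shape = 1) is
identical to the constant baseline at `lambda0 = rate` to 1e-8, which the
tests assert.

Optimisation is multi-start L-BFGS-B (default 5 seeded starts; the first
two are deterministic heuristics — `s` at 1 and near 0, baseline at the
events/exposure rate — and the rest random perturbations) on transformed
scales: `s` linear with a [0, s_max] box (s_max default 1e3), ILV
coefficients unbounded, baseline parameters on log scales. Gradient
tolerance 1e-8, tie between starts resolved by best likelihood. Task types
with zero events under the "different" constraint get `s` pinned at 0 with
a warning rather than a free, unidentified parameter.

Ties in event times (times are scored to the nearest second) are resolved
before fitting by adding `index * 1e-6 s` in input order (the scoring
order of the video record) or, for sensitivity analysis, in seeded random
order; original times are retained as metadata.

Censoring: non-acquirers are right-censored at the trial end; when no
trial end is recorded, the diffusion's last event time is used with a
logged warning. This is the conservative, data-driven choice given that
trial durations are often not archived.

### Profile CIs and %ST

The 95% CI on any parameter is the set of values whose profile
log-likelihood (nuisance parameters re-optimised at each point) lies
within chi2_1(0.95)/2 = 1.92 of the maximum, found by doubling-step
bracketing plus Brent root-finding on each side. For `s` the lower bound
is clipped at 0; an upper bound that never crosses the threshold is capped
at s_max and flagged open.

%ST for each non-innovator event is the social share of the acquirer's
relative rate (`s T/(s T + exp(Bx))` additive; `s T/(s T + 1)`
multiplicative and no-ILV), averaged within task type (pooled across
tasks under the "same" constraint, where one value is reported for all
tasks). Its CI re-evaluates the shares at the two profile bounds of `s`
with nuisance parameters at their profile optima — propagation from the
`s` profile rather than a full two-dimensional profile, which the
reporting convention for this statistic does not specify further.

## Model competition

The candidate space crosses {additive, multiplicative} x non-empty ILV
subsets plus the no-ILV social form, with same/different `s`,
constant/gamma baselines and social/group networks, plus asocial models
for every ILV subset and baseline: 64 models for two ILVs and five task
types (36 unique models when a single task type makes the s-constraint
degenerate). AIC (not AICc) ranks models; AICc is available behind a flag.
Akaike weights normalise over all successfully fitted models; failed fits
are dropped from the normalisation with a warning instead of aborting the
competition. Support tables sum weights over any partition of the space
and render cells below 0.01% as "<0.01" while machine output keeps full
precision.

## Latency GLMM

Interact-to-solve latency (first solve minus first interaction per
individual, round and task type) is gamma-distributed with log link:
`y ~ Gamma(alpha, mean exp(x'beta + u_i))`, `u_i ~ N(0, sigma_id^2)` per
individual. Task types never solved contribute no row — a gamma GLMM
cannot represent right-censoring, and no censoring-aware convention exists
for this statistic. A solve recorded at the same second as the first touch
is kept at a nominal 0.5 s latency to stay inside the gamma support.

The marginal likelihood integrates `u_i` out with adaptive Gauss-Hermite
quadrature (20 probabilists' nodes; per-individual mode by Newton on the
log-concave integrand exponent, curvature-scaled nodes). The fit is full
ML — not REML — so AIC is comparable across fixed-effect subsets, which
the selection design requires. Fitting is L-BFGS-B on
(beta, log alpha, log sigma), seeded from a gamma GLM; a random-intercept
SD estimated below 1e-3 is reported as a singular 0 with a flag.
Parameter count is fixed effects + gamma shape + random-intercept
variance, so the full model with five task levels has df = 10.

Subset selection fits all 2^4 = 16 combinations of {round, age, sex,
task type} (task type categorical, level 1 reference; random intercept
always present), ranks by AIC, and forms the top set from models with
dAIC <= 2 after the nesting rule: discard any candidate whose fixed
effects strictly contain another candidate's with an AIC at least as low,
then renormalise weights over the retained set. The rule is cited by name
in the field without mechanics; this formalisation is one admissible
reading and is unit-tested on hand-worked examples, including the case
where a superset with strictly lower AIC is retained.

## Synthetic studies

The generator emulates the emulated study design: three groups of 12, 12
and 5 animals (two family groups and one sibling group), sexes
Bernoulli(0.5), ages a mixture of pups (uniform 0.25-0.75 yr, probability
0.3) and adults (uniform 1-8 yr), round-2 ages shifted by 0.33 yr
(~4 months between presentation rounds). Scans: 180 per round (15
observation hours at one scan per 5 min), dyadic association
probabilities `p_ij ~ Beta(0.7, 8)` and per-scan parties as connected
components of Bernoulli edge draws. The Beta parameters were calibrated by
pilot simulation so the study-median social differentiation falls in the
configured 0.3-0.6 band typical of such groups; individual networks from
the 5-animal group (10 dyads) scatter more widely, which is sampling
noise, not a generator property.

Diffusions are generated by the exact competing-risks counterpart of the
TADA model: waiting times solve
`sum_i R_i [Lambda0(t) - Lambda0(t_now)] = Exp(1)` via the gamma
survival-function inverse (plain Gillespie sampling under the constant
baseline), acquirers drawn proportional to `R_i`. Default truths use the
magnitudes such experiments report — interaction transmission rate 5.5,
solving 1.5, age multiplier 1.15x/yr, gamma baseline shape 2 with mean
asocial waiting time 600 s, trial horizon 7200 s — as plausible generator
settings, never as test oracles. Interact and solve diffusions are
generated independently; solve event times are offset by the same
individual's interact time so interact-to-solve latencies are well
defined, and individuals who never interacted cannot solve.

Latency truth: log-scale coefficients (intercept 3.0, round-2 effect
-0.9, sex 0.17, age 0, task offsets 0/1.0/3.0/3.2/2.6), individual SD
0.3, gamma shape 2 — a round-2 reduction to roughly 40% of round-1
latencies with females slower, matching the qualitative structure such
studies find.

All generators are pure functions of (config, seed); the study composer
derives named substreams (roster, scans, diffusion, latency) from one
root seed so each stage is independently reproducible.

### What the generator does not emulate

Scan samples are serially independent, unlike real 5-minute samples within
an hour; this is harmless downstream because the diffusion analysis
consumes only the index matrix, not sample counts. Networks are static
within a round; there is no observation error on event times; repeat
solves after the first are out of scope. Passing tests therefore show the
inference machinery is correct and calibrated under the model's own
assumptions, not that the model is correct for any particular real group.

## Problem sizes in the test suite

The acceptance-style tests use the study-scale design (29 animals, 15
diffusions per behaviour and round) with 100 replicates for recovery and
CI coverage, 50 replicates for model-class recovery against a reduced
candidate set spanning the rival classes (both network kinds for all
social forms plus the asocial model), 1000 null replicates for Mantel
calibration at 199 permutations, and 2000 replicates for the
acquisition-order null. Heavy multi-replicate loops fit with 2 seeded
starts; the likelihood surfaces involved are well behaved and the
deterministic heuristic starts dominate, which the multi-start agreement
diagnostic confirms on the default 5-start fits.

## Known limitations

- Per-group baselines and time-varying networks within a diffusion are
  not supported.
- %ST intervals propagate only the `s` profile, not joint uncertainty.
- The gamma GLMM supports a single scalar random intercept (individual
  identity); crossed or nested random effects are out of scope.
- The order-only (OADA) likelihood and discrete-time TADA are not
  implemented.
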