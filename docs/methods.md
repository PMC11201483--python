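# Methods

## Model and assumptions

The data are assumed to come from a linear structural equation model
over a directed acyclic graph G on n variables: each variable is a
weighted sum of its parents plus an independent disturbance,
`x_i = w_i' pa(x_i) + u_i`. Three generating mechanisms are supported
by the simulator and accepted by the learner:

| mechanism | weights | noise | character |
|---|---|---|---|
| SEM 1 | `±1 + N(0,1)/4` | `N(0,1)` | linear Gaussian |
| SEM 2 | `Uniform(0.2, 1)` | `N(0,1)` | linear Gaussian |
| SEM 3 | `±1 + N(0,1)/4` | `Uniform(-1,1)` | linear non-Gaussian |

Weights are drawn once per dataset. Because the disturbances are
homoscedastic and uncorrelated, (a) zero partial correlation is
equivalent to conditional independence, which justifies the constraint
phase, and (b) OLS is the best linear unbiased estimator, which
justifies the scoring model. Equal noise variances also make the exact
DAG (not merely its Markov equivalence class) the score maximiser in
the large-sample limit, because the score fixes the residual variance
at one rather than profiling it per node: reversing a true edge
inflates the total residual sum of squares.

## Conditional-independence testing

Partial correlations are computed by inverting the (sub-)correlation
matrix over `{i, j} ∪ Z`: with `P = R^-1`, `rho_{ij|Z} =
-P_ij / sqrt(P_ii P_jj)`; this equals the correlation of the two OLS
residual vectors. Significance uses `t = rho sqrt((m-n)/(1-rho^2))`,
approximately Student-t with `m - n` degrees of freedom at large m, and
the BIC-approximation Bayes factor of the independence hypothesis

    BF01 = sqrt(m) * (1 + t^2/(m-n))^(-m/2),

with dependence declared when `BF01 < k`. Choices worth noting:

- **Degrees of freedom** are `m - n` with n the total variable count,
  for both full and local tests; at the m ≥ 1000 regimes targeted the
  difference from `m - |Z| - 2` is negligible.
- **BF01 functional form**: BF01 is strictly decreasing in |t|, so any
  variant of the approximation differs only by an effective threshold;
  the form lives behind a single function so it can be swapped.
- **Ties** at `BF01 == k` resolve to independence (strict inequality).
- **Singular correlation matrices** (duplicate columns) get a ridge of
  1e-10 on the diagonal with a logged warning; failure after that is a
  hard error.
- The tester accepts either a data matrix or an analytic covariance
  with a nominal sample size; the latter is how population-limit
  properties are tested without sampling noise.

## Constraint phase

Stage 1 builds the Markov random field from full partial correlations;
it approximates the moral graph under faithfulness and seeds both the
GSS and LSS. Stage 2 tries to separate each MRF edge: the initial
conditioning set is the *smaller* of the two endpoint neighbourhoods
(one full neighbourhood is sufficient when a separator within the
blankets exists); each round computes the set of conditioning nodes
with an open simple path — `Zm` such that both `rho_{i,Zm|Z∪{j}\Zm}`
and `rho_{j,Zm|Z∪{i}\Zm}` are significant — and removes the one whose
removal leaves the fewest open nodes (ties: lowest index), re-testing
independence after every removal. The greedy search is not guaranteed
complete; the test suite calibrates it against exhaustive subset search
over the smaller blanket on analytic populations and requires ≥ 95%
agreement where a separator exists. Stage 3 applies standard
unshielded-collider logic to each separated pair: a common neighbour
excluded from the final separating set whose inclusion restores
dependence is a collider, contributing two directed prior edges. The
prior edge set is kept acyclic by dropping any later pair that would
close a cycle (logged); false colliders at finite samples make this
occasionally necessary. Edges that could not be separated stay in both
GSS and LSS.

## Scoring

The fitness is the decomposable BIC with OLS plug-in parameters:
`score(G) = Σ_j -(RSS_j/2 + |pa(j)|/2 ln m)`, natural logarithms,
columns mean-centered once at load (the regressions carry no
intercept). The RSS/2 convention is the unit-variance Gaussian negative
log-likelihood without constants; a `nll_factor` switch (default 0.5)
exposes the raw-RSS alternative. All fits go through the precomputed
Gram matrix, so a fit with p parents costs O(p^3) independent of m, and
per-(node, parent-set) results are cached. Moves are scored
incrementally: add/delete touches one node, reversal two; an identity
test checks 1000 random deltas against full recomputation to 1e-8.

## Operator library

Thirteen operators act on subgroups of individuals (DAG + fitness +
personal best). Design decisions where the lineage algorithms leave the
mechanics open:

- The learning rule shared by the cognitive, cooperative, moth-flame,
  and teaching-learning operators adopts each edge-difference from the
  guide independently with probability equal to the acceleration
  coefficient, in random order, skipping cycle-creating adoptions. The
  cooperative coefficient grows linearly 0.1 → 0.5 over the run.
- The operators affected by the complete-search-space switch are the
  exploration/restart ones — mutation, elimination-dispersal, scout
  bees; chemotaxis and the bee local-search operators stay on the GSS,
  neighbourhood perturbation on the LSS.
- Elimination-dispersal fires with probability `c3 = 0.1 + 0.9 L/Lmax`
  (L = global stagnation count) and restarts one node's parent set of
  the subgroup best: strip, dry-run addition chemotaxis to collect
  candidates, re-add in order of decreasing |full partial correlation|
  when the score improves, greedy deletion, one reversion pass.
- Worker bees make one keep-better random GSS move per individual;
  onlookers apply the same move to individuals sampled proportionally
  to fitness rank; scouts trigger per individual after `lm = 20`
  iterations without personal-best improvement.
- Pruning deletes every edge contributing less than `mu = ln m` to the
  score, scanning edges once in a fixed order.
- Greedy accepts inside operators mean `delta > 0`; a
  `strict_mu_improvement` flag preserves the alternative reading where
  `mu` gates improvement everywhere.
- Node choices are uniform at random, fresh per individual per call.
  All randomness flows through the engine's seeded generator.

## Engine

Population `nPop = 50` split into `sn = 5` subgroups; each subgroup
owns an independent choice-function state. Per iteration each subgroup
selects one operator (`F = phi*f1 + phi*f2 + delta*f3`, ties uniform),
applies it, and records the call with the improvement measured on the
subgroup's best fitness. Improvement rewards `phi = 0.99`;
deterioration decays it by 0.01 to a floor of 0.01, `delta = 1 - phi`.
Raw improvement rates I/T are rescaled into `[0.1 tbar, 0.2 tbar]`
(tbar = mean call duration) before entering f1/f2 — without this,
fitness deltas (often thousands) swamp the idle-time clock and the
strategy never explores. f1/f2 store already-rescaled contributions;
history is not retroactively re-rescaled. The pair rate f2 divides by
the sum of the two consecutive calls' durations.

Initialization seeds every individual with the v-structure prior DAG
and walks `r ~ Uniform{1..n}` first-improvement hill-climbing moves in
the GSS, scanning legal moves in random order; first-improvement
(rather than steepest) keeps the population diverse despite the shared
starting point. Migration runs every `min(100, n)` iterations: subgroup
bests move one step around a ring, replacing the target's worst
individual, unless the inbreeding rate — the fraction of subgroup bests
within Hamming distance 4 of the global best — exceeds 0.6. When the
global best stalls for `Lmax = 2n` iterations the one-shot switching
operator opens the complete search space to the global operators and
resets the counter; the run ends at the next `Lmax`-stall or at
`MaxIt = 5000`. With `time_mode="iterations"` (f3 counted in calls,
durations = 1) runs are bit-for-bit reproducible for a fixed seed; the
default wall-clock mode matches the motivation of the f3 term but makes
operator selection timing-dependent.

## Synthetic data and what passing tests show

The simulator emulates the three SEM mechanisms over random DAGs drawn
by sampling a uniform topological order and including forward pairs
independently (edge probability `avg_degree/(n-1)`). It does not
emulate latent confounders, selection bias, measurement error, missing
data, discrete variables, or nonlinear mechanisms — results on it bound
what to expect on real data from above. The analytic covariance
`Σ = (I-W)^-T D (I-W)^-1` provides exact population oracles for the
CI-test and constraint-phase suites.

Problem sizes in the test and acceptance suites — 200 population SEMs
with n ≤ 8, 20 four-node datasets at m = 500 (exhaustive enumeration of
all 543 DAGs), five 20-node datasets at m = 1000 — were chosen so each
check isolates one claim at a scale where an independent oracle
(d-separation, exhaustive subset search, exhaustive DAG enumeration,
full score recomputation) is computable exactly.

## Known limitations

- The greedy separating-set search can miss separators (calibrated, not
  guaranteed); missed separators leave spurious LSS edges and may miss
  v-structures.
- Finite-sample CI errors can produce contradictory collider priors;
  the acyclicity guard drops later pairs rather than re-optimising the
  set.
- The score assumes unit noise variance; heteroscedastic data shift the
  score optimum away from the true DAG.
- Wall-clock f3 makes default runs non-reproducible in their operator
  sequence (not in their invariants); use iteration mode for exact
  reproducibility.
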