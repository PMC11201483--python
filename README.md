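# causalhh

Causal DAG discovery for continuous data generated by **linear structural
equation models** (SEMs), aimed at systems-biology and network-inference
settings where each variable is a weighted sum of its graph parents plus
independent noise:

```
x_i = w_i' pa(x_i) + u_i
```

The package couples two phases:

1. **SPPC — search-space restriction by partial correlation.**
   For linear SEMs with homoscedastic uncorrelated noise, a vanishing
   partial correlation `rho_{ij|Z}` is equivalent to conditional
   independence. SPPC first connects every pair whose *full* partial
   correlation is significant (judged by the Bayes factor
   `BF01 = sqrt(m) (1 + t^2/(m-n))^{-m/2}` of the independence
   hypothesis, with `t = rho / sqrt((1-rho^2)/(m-n))`; a pair is
   dependent when `BF01 < k`, default `k = 0.01`). This Markov random
   field becomes the **global search space (GSS)**. A greedy
   open-simple-path search then looks for separating sets of MRF edges;
   separable edges are spurious spouse links created by moralisation and
   are dropped from the **local search space (LSS)**, and the colliders
   responsible yield a directed **v-structure prior V**.

2. **MCFHH — multi-population choice-function hyper-heuristic.**
   A population of candidate DAGs, split into subgroups, is evolved by
   13 low-level operators derived from PSO, bacterial foraging, bee
   colony, moth-flame, and teaching-learning optimisers, plus
   prior-injection, pruning, and LSS-perturbation operators. Each
   subgroup selects operators with a choice function
   `F = phi*f1 + phi*f2 + delta*f3` (past performance, pairwise synergy,
   idle time) with reward/punish weight dynamics and a rate-rescaling
   fix that keeps fitness deltas commensurate with call times.
   Fitness is the decomposable BIC under ordinary-least-squares fits,
   `score = sum_j -(RSS_j/2 + |pa(j)|/2 ln m)` (higher is better).
   Subgroups exchange their best solutions over a migration ring
   throttled by an inbreeding-rate check, and a one-shot switching
   operator widens the global operators to the complete space when the
   search stalls.

## Worked example

Simulate a 20-node linear-Gaussian dataset, learn the structure, and
evaluate it against the ground truth:

```bash
causalhh simulate --random-dag 20,2.5 --sem 1 --m 1000 --seed 0 \
    --out data.csv --out-truth truth.txt
causalhh learn --data data.csv --seed 0 --out learned.txt
causalhh evaluate --learned learned.txt --truth truth.txt --data data.csv
```

which prints (learning step, then evaluation):

```
best score -9995.7920 after 81 iterations
{
  "AD": 0,
  "DD": 1,
  "RD": 0,
  "precision": 1.0,
  "recall": 0.9565217391304348,
  "f1": 0.9777777777777777,
  "learned_score": -9995.792015504438,
  "sbs": -9976.065863210155
}
```

By default the choice function's idle-time term runs on wall-clock
time, so the iteration count can vary between runs of `learn`; pass a
config with `"time_mode": "iterations"` for bit-for-bit reproducible
runs under a fixed seed.

`AD`/`DD`/`RD` count skeleton edges wrongly added, deleted, and
oppositely oriented; `f1` scores exactly oriented directed edges;
`learned_score` is the BIC of the output and `sbs` the BIC of the true
network on the same data (here one weak edge was dropped because the
data support the smaller model). The same functionality is available as
a library — see `causalhh.run`, `causalhh.run_sppc`, and
`causalhh.evaluate`.

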