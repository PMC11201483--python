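"""Multi-population choice-function hyper-heuristic engine.

The population is split into ``sn`` subgroups, each running its own
choice function over the 13-operator portfolio under all-moves
acceptance.  Subgroups communicate through a ring migration operator
throttled by an inbreeding-rate check, and a one-shot search-space
switching operator widens the global operators from the restricted GSS
to the complete space when the best score stalls for ``Lmax``
iterations; the run ends when it stalls for ``Lmax`` more, or at
``MaxIt``.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np

from causalhh.choice_function import ChoiceFunctionState, record_call, select, update_weights
from causalhh.llh_library import OPERATORS, Individual, OperatorContext, force_prior_edges
from causalhh.model_core import DataMatrix, creates_cycle, hamming_distance
from causalhh.partial_correlation import CITester
from causalhh.scoring import ScoreContext
from causalhh.sppc import SppcResult, run_sppc

logger = logging.getLogger(__name__)


@dataclass
class EngineConfig:
    """Tunable parameters; defaults follow the method's standard setting.

    ``lmax`` and ``migration_interval`` default to 2n and min(100, n)
    respectively and are resolved against the data at run time;
    ``mu`` is fixed at ln m by the scoring context.
    """

    k: float = 0.01
    n_pop: int = 50
    sn: int = 5
    lmax: int | None = None
    max_it: int = 5000
    lm: int = 20
    zj: float = 0.5
    migration_interval: int | None = None
    inbreed_dist: int = 4
    inbreed_cap: float = 0.6
    seed: int = 0
    nll_factor: float = 0.5
    strict_mu_improvement: bool = False
    use_switching: bool = True
    time_mode: str = "wall"  # "wall" or "iterations" (fully deterministic)

    def resolved_lmax(self, n: int) -> int:
        return self.lmax if self.lmax is not None else 2 * n

    def resolved_migration_interval(self, n: int) -> int:
        if self.migration_interval is not None:
            return self.migration_interval
        return min(100, n)


@dataclass
class RunResult:
    best: np.ndarray
    best_fitness: float
    trace: list[float]
    operator_log: list[dict]
    switched_at: int | None
    iterations: int
    sppc: SppcResult


def init_population(
    priors, spaces, score: ScoreContext, cfg: EngineConfig, rng: np.random.Generator
) -> list[Individual]:
    """Seed every individual with the v-structure prior, then walk
    r ~ U{1..n} first-improvement hill-climbing moves within the GSS
    (moves scanned in random order; only strict improvements accepted)."""
    n = score.n
    n_pop = cfg.n_pop
    if n_pop % cfg.sn:
        n_pop += cfg.sn - n_pop % cfg.sn
        logger.warning("population padded to %d for %d subgroups", n_pop, cfg.sn)
    base = priors.as_adjacency(n)
    base_fitness = score.graph_score(base)
    gss = spaces.gss.adjacency
    population = []
    for _ in range(n_pop):
        ind = Individual(g=base.copy(), fitness=base_fitness)
        for _ in range(int(rng.integers(1, n + 1))):
            if not _hill_climb_step(ind, score, gss, rng):
                break
        ind.pbest_g = ind.g.copy()
        ind.pbest_fitness = ind.fitness
        population.append(ind)
    return population


def _hill_climb_step(
    ind: Individual, score: ScoreContext, gss: np.ndarray, rng: np.random.Generator
) -> bool:
    """Apply the first strictly improving move found in a random scan of
    the legal GSS moves; False when none improves."""
    g = ind.g
    moves: list[tuple[str, int, int]] = []
    for i, j in np.argwhere(gss & ~g & ~g.T).tolist():
        moves.append(("add", i, j))
    for i, j in np.argwhere(g).tolist():
        moves.append(("delete", i, j))
        moves.append(("reverse", i, j))
    if not moves:
        return False
    for idx in rng.permutation(len(moves)).tolist():
        kind, i, j = moves[idx]
        if kind == "add" and creates_cycle(g, i, j):
            continue
        if kind == "reverse":
            g[i, j] = False
            bad = creates_cycle(g, j, i)
            g[i, j] = True
            if bad:
                continue
        delta = score.delta_score(g, (kind, i, j))
        if delta > 0:
            if kind == "add":
                g[i, j] = True
            elif kind == "delete":
                g[i, j] = False
            else:
                g[i, j] = False
                g[j, i] = True
            ind.fitness += delta
            return True
    return False


def migrate(
    subgroups: list[list[Individual]],
    gbest_g: np.ndarray,
    cfg: EngineConfig,
) -> bool:
    """Ring migration of subgroup bests, skipped entirely when the
    inbreeding rate (fraction of subgroup bests within Hamming distance
    ``inbreed_dist`` of the global best) exceeds ``inbreed_cap``."""
    bests = [max(sg, key=lambda ind: ind.fitness) for sg in subgroups]
    close = sum(
        hamming_distance(b.g, gbest_g) < cfg.inbreed_dist for b in bests
    )
    rate = close / len(subgroups)
    if rate > cfg.inbreed_cap:
        return False
    sn = len(subgroups)
    for g_idx in range(sn):
        donor = bests[g_idx]
        target = subgroups[(g_idx + 1) % sn]
        worst_idx = min(range(len(target)), key=lambda t: (target[t].fitness, -t))
        target[worst_idx] = Individual(
            g=donor.g.copy(),
            fitness=donor.fitness,
            pbest_g=donor.pbest_g.copy(),
            pbest_fitness=donor.pbest_fitness,
            stagnation=donor.stagnation,
        )
    return True


def run(data: DataMatrix, cfg: EngineConfig | None = None, sppc_result: SppcResult | None = None) -> RunResult:
    """Full pipeline: constraint phase (unless supplied), population
    initialization, per-subgroup choice-function loops, migration,
    switching, and termination."""
    cfg = cfg or EngineConfig()
    rng = np.random.default_rng(cfg.seed)
    n = data.n
    lmax = cfg.resolved_lmax(n)
    mig_interval = cfg.resolved_migration_interval(n)

    if sppc_result is None:
        tester = CITester.from_data(data, cfg.k)
        sppc_result = run_sppc(tester, cfg.k)
    spaces = sppc_result.spaces
    score = ScoreContext(data, nll_factor=cfg.nll_factor)
    ctx = OperatorContext(
        spaces=spaces,
        score=score,
        priors=sppc_result.priors,
        rng=rng,
        full_partials_abs=np.abs(CITester.from_data(data, cfg.k).full_partials()),
        max_it=cfg.max_it,
        Lmax=lmax,
        lm=cfg.lm,
        zj=cfg.zj,
        strict_mu_improvement=cfg.strict_mu_improvement,
    )

    population = init_population(sppc_result.priors, spaces, score, cfg, rng)
    per = len(population) // cfg.sn
    subgroups = [population[i * per : (i + 1) * per] for i in range(cfg.sn)]
    cf_states = [
        ChoiceFunctionState(operators=tuple(OPERATORS)) for _ in range(cfg.sn)
    ]

    gbest = max(population, key=lambda ind: ind.fitness)
    gbest_g, gbest_fitness = gbest.g.copy(), gbest.fitness
    trace: list[float] = []
    op_log: list[dict] = []
    L = 0
    switched_at: int | None = None
    iteration = 0
    wall = cfg.time_mode == "wall"

    for iteration in range(1, cfg.max_it + 1):
        ctx.iteration = iteration
        ctx.L = L
        for g_idx, subgroup in enumerate(subgroups):
            state = cf_states[g_idx]
            op = select(state, rng)
            ctx.subgroup_best = max(subgroup, key=lambda ind: ind.fitness)
            prev_best = ctx.subgroup_best.fitness
            t0 = time.perf_counter() if wall else 0.0
            OPERATORS[op](subgroup, ctx)
            duration = (time.perf_counter() - t0) if wall else 1.0
            new_best = max(ind.fitness for ind in subgroup)
            delta = new_best - prev_best
            record_call(state, op, state.last_op, delta, duration)
            update_weights(state, delta > 0)
            for ind in subgroup:
                ind.note_pbest()
            op_log.append(
                {
                    "iteration": iteration,
                    "subgroup": g_idx,
                    "operator": op,
                    "delta": delta,
                    "duration": duration,
                    "phi": state.phi,
                }
            )

        it_best = max(population, key=lambda ind: ind.fitness)
        if it_best.fitness > gbest_fitness + 1e-12:
            gbest_g, gbest_fitness = it_best.g.copy(), it_best.fitness
            L = 0
        else:
            L += 1
        trace.append(gbest_fitness)

        if iteration % mig_interval == 0:
            migrate(subgroups, gbest_g, cfg)

        if L >= lmax:
            if cfg.use_switching and switched_at is None:
                spaces.css_active = True
                switched_at = iteration
                L = 0
                logger.info("switched to the complete search space at iteration %d", iteration)
            else:
                break

    logger.info(
        "engine finished after %d iterations; best score %.4f", iteration, gbest_fitness
    )
    return RunResult(
        best=gbest_g,
        best_fitness=gbest_fitness,
        trace=trace,
        operator_log=op_log,
        switched_at=switched_at,
        iterations=iteration,
        sppc=sppc_result,
    )
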