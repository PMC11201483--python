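"""The 13 low-level heuristics of the hyper-heuristic portfolio.

Each operator maps a subgroup of individuals (candidate DAGs with cached
fitness) to a modified subgroup.  The portfolio is drawn from several
swarm-intelligence lineages: PSO-style mutation/cognitive/cooperative
learning, bacterial-foraging chemotaxis and elimination-dispersal,
bee-colony worker/onlooker/scout phases, moth-flame and teaching-learning
learners, plus three bespoke operators (expert-knowledge injection of the
v-structure prior, BIC-threshold pruning, and LSS neighbourhood
perturbation).

Contract shared by all operators: every produced graph is acyclic, every
edge's unordered pair lies in the operator's designated search space
(GSS, LSS, or the complete space once switching has fired for the global
operators), and fitness fields track the score incrementally.  Infeasible
proposals (cycles, no candidates) are skipped, never repaired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from causalhh.model_core import SearchSpaces, VStructurePrior, creates_cycle, parents
from causalhh.scoring import ScoreContext

MOVE_KINDS = ("add", "delete", "reverse")


@dataclass
class Individual:
    """A candidate DAG with score bookkeeping and a personal best."""

    g: np.ndarray
    fitness: float
    pbest_g: np.ndarray = None
    pbest_fitness: float = -math.inf
    stagnation: int = 0

    def __post_init__(self) -> None:
        if self.pbest_g is None:
            self.pbest_g = self.g.copy()
            self.pbest_fitness = self.fitness

    def note_pbest(self) -> None:
        if self.fitness > self.pbest_fitness:
            self.pbest_g = self.g.copy()
            self.pbest_fitness = self.fitness
            self.stagnation = 0
        else:
            self.stagnation += 1


@dataclass
class OperatorContext:
    """Shared state the engine hands to every operator call."""

    spaces: SearchSpaces
    score: ScoreContext
    priors: VStructurePrior
    rng: np.random.Generator
    full_partials_abs: np.ndarray
    iteration: int = 0
    max_it: int = 5000
    L: int = 0
    Lmax: int = 100
    lm: int = 20
    zj: float = 0.5
    c: float = 0.1
    strict_mu_improvement: bool = False
    subgroup_best: Individual | None = None

    @property
    def mu(self) -> float:
        return self.score.log_m

    @property
    def c3(self) -> float:
        """Firing probability of elimination-dispersal: 0.1 + 0.9 L/Lmax."""
        return 0.1 + 0.9 * min(self.L, self.Lmax) / self.Lmax

    @property
    def improve_eps(self) -> float:
        # with the strict reading, greedy accepts require delta > mu
        return self.mu if self.strict_mu_improvement else 0.0

    def cooperative_c(self) -> float:
        return 0.1 + 0.4 * self.iteration / self.max_it

    def global_space(self) -> np.ndarray:
        """Allowed pairs for the global (exploration) operators."""
        n = self.spaces.gss.n
        if self.spaces.css_active:
            return ~np.eye(n, dtype=bool)
        return self.spaces.gss.adjacency

    def gss_space(self) -> np.ndarray:
        return self.spaces.gss.adjacency

    def lss_space(self) -> np.ndarray:
        return self.spaces.lss.adjacency


# -- shared mechanics ------------------------------------------------------


def _apply(ind: Individual, ctx: OperatorContext, kind: str, i: int, j: int) -> float:
    """Apply a legal move and update the fitness incrementally."""
    delta = ctx.score.delta_score(ind.g, (kind, i, j))
    if kind == "add":
        ind.g[i, j] = True
    elif kind == "delete":
        ind.g[i, j] = False
    else:
        ind.g[i, j] = False
        ind.g[j, i] = True
    ind.fitness += delta
    return delta


def _propose_random_move(
    ind: Individual, ctx: OperatorContext, allowed: np.ndarray
) -> tuple[str, int, int] | None:
    """One random add/delete/reverse within the allowed pair set.

    The move kind is drawn uniformly among the kinds with candidates;
    a cycle-creating pick is discarded (the proposal is skipped).
    """
    g = ind.g
    add_mask = allowed & ~g & ~g.T
    edges = np.argwhere(g)
    options = []
    if add_mask.any():
        options.append("add")
    if edges.size:
        options.extend(["delete", "reverse"])
    if not options:
        return None
    kind = str(ctx.rng.choice(options))
    if kind == "add":
        cells = np.argwhere(add_mask)
        i, j = cells[ctx.rng.integers(len(cells))]
        if creates_cycle(g, int(i), int(j)):
            return None
        return ("add", int(i), int(j))
    i, j = edges[ctx.rng.integers(len(edges))]
    if kind == "reverse":
        g[i, j] = False
        bad = creates_cycle(g, int(j), int(i))
        g[i, j] = True
        if bad:
            return None
    return (kind, int(i), int(j))


def _adopt_differences(
    ind: Individual, guide: np.ndarray, ctx: OperatorContext, c: float
) -> None:
    """PSO-lineage learning rule: each edge-difference from the guide is
    adopted independently with probability c, in random order; adoptions
    that would close a cycle are skipped."""
    diff = np.argwhere(ind.g != guide)
    if not diff.size:
        return
    order = ctx.rng.permutation(len(diff))
    for idx in order:
        i, j = int(diff[idx, 0]), int(diff[idx, 1])
        if ind.g[i, j] == guide[i, j]:
            continue  # resolved by an earlier adoption
        if ctx.rng.random() >= c:
            continue
        if guide[i, j]:
            if ind.g[j, i] or creates_cycle(ind.g, i, j):
                continue
            _apply(ind, ctx, "add", i, j)
        else:
            _apply(ind, ctx, "delete", i, j)


def _chemotaxis_passes(
    ind: Individual, ctx: OperatorContext, node: int, space: np.ndarray
) -> None:
    """Greedy addition, deletion, then reversion on one node's parent set."""
    eps = ctx.improve_eps
    # addition: best improving parent until none improves
    while True:
        cand = np.flatnonzero(space[:, node] & ~ind.g[:, node] & ~ind.g[node, :])
        best, best_delta = None, eps
        for i in cand.tolist():
            if creates_cycle(ind.g, i, node):
                continue
            d = ctx.score.delta_add(ind.g, i, node)
            if d > best_delta:
                best, best_delta = i, d
        if best is None:
            break
        _apply(ind, ctx, "add", best, node)
    # deletion: drop the worst-contributing parent while that improves
    while True:
        best, best_delta = None, eps
        for i in parents(ind.g, node):
            d = ctx.score.delta_delete(ind.g, i, node)
            if d > best_delta:
                best, best_delta = i, d
        if best is None:
            break
        _apply(ind, ctx, "delete", best, node)
    # reversion: one pass over the surviving parents
    for i in parents(ind.g, node):
        ind.g[i, node] = False
        bad = creates_cycle(ind.g, node, i)
        ind.g[i, node] = True
        if bad:
            continue
        if ctx.score.delta_reverse(ind.g, i, node) > eps:
            _apply(ind, ctx, "reverse", i, node)


# -- the 13 operators ------------------------------------------------------


def op_mutation(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """One random move per individual within the global space, accepted
    unconditionally (all-moves acceptance)."""
    allowed = ctx.global_space()
    for ind in subgroup:
        move = _propose_random_move(ind, ctx, allowed)
        if move is not None:
            _apply(ind, ctx, *move)


def op_cognitive_personal(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """Learn toward the personal best with coefficient c."""
    for ind in subgroup:
        _adopt_differences(ind, ind.pbest_g, ctx, ctx.c)


def op_cooperative_global(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """Learn toward the subgroup best; the coefficient rises linearly
    from 0.1 to 0.5 over the run to avoid premature convergence."""
    guide = ctx.subgroup_best.g.copy()
    c = ctx.cooperative_c()
    for ind in subgroup:
        _adopt_differences(ind, guide, ctx, c)


def op_chemotactic(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """Bacterial chemotaxis on one random node's parent set per
    individual: greedy addition, deletion, reversion within the GSS."""
    space = ctx.gss_space()
    for ind in subgroup:
        node = int(ctx.rng.integers(ctx.score.n))
        _chemotaxis_passes(ind, ctx, node, space)


def op_elimination_dispersal(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """Local restart of the subgroup's best structure at one node.

    Fires with probability c3 (rising with global stagnation).  The
    node's parents are stripped; an addition-chemotaxis dry run collects
    potential parents, which are re-added in order of decreasing absolute
    full partial correlation when they improve the score; a greedy
    deletion pass and one reversion pass clean up.
    """
    if ctx.rng.random() >= ctx.c3:
        return
    best = ctx.subgroup_best
    space = ctx.global_space()
    node = int(ctx.rng.integers(ctx.score.n))
    # (1) strip the node's parents
    for i in parents(best.g, node):
        _apply(best, ctx, "delete", i, node)
    # (2) dry-run addition chemotaxis to collect a candidate parent set
    probe = Individual(g=best.g.copy(), fitness=best.fitness)
    _chemotaxis_passes(probe, ctx, node, space)
    candidates = list(parents(probe.g, node))
    candidates.sort(key=lambda i: -ctx.full_partials_abs[i, node])
    # (3) re-add candidates that improve the score
    for i in candidates:
        if best.g[i, node] or best.g[node, i] or creates_cycle(best.g, i, node):
            continue
        if ctx.score.delta_add(best.g, i, node) > ctx.improve_eps:
            _apply(best, ctx, "add", i, node)
    # (4) greedy deletion while it improves, (5) one reversion pass
    eps = ctx.improve_eps
    while True:
        worst, worst_delta = None, eps
        for i in parents(best.g, node):
            d = ctx.score.delta_delete(best.g, i, node)
            if d > worst_delta:
                worst, worst_delta = i, d
        if worst is None:
            break
        _apply(best, ctx, "delete", worst, node)
    for i in parents(best.g, node):
        best.g[i, node] = False
        bad = creates_cycle(best.g, node, i)
        best.g[i, node] = True
        if not bad and ctx.score.delta_reverse(best.g, i, node) > eps:
            _apply(best, ctx, "reverse", i, node)


def _worker_move(ind: Individual, ctx: OperatorContext, space: np.ndarray) -> None:
    move = _propose_random_move(ind, ctx, space)
    if move is None:
        return
    delta = ctx.score.delta_score(ind.g, move)
    if delta > 0:  # keep the better of old and new
        _apply(ind, ctx, *move)


def op_worker_bees(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """One keep-better neighbourhood move per individual within the GSS."""
    space = ctx.gss_space()
    for ind in subgroup:
        _worker_move(ind, ctx, space)


def op_onlooker_bees(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """Keep-better moves on individuals sampled proportionally to fitness
    rank (best rank gets the highest probability)."""
    space = ctx.gss_space()
    order = sorted(range(len(subgroup)), key=lambda idx: subgroup[idx].fitness)
    ranks = np.empty(len(subgroup))
    for r, idx in enumerate(order):
        ranks[idx] = r + 1  # worst gets 1, best gets len(subgroup)
    probs = ranks / ranks.sum()
    picks = ctx.rng.choice(len(subgroup), size=len(subgroup), p=probs)
    for idx in picks.tolist():
        _worker_move(subgroup[idx], ctx, space)


def op_scout_bees(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """Stagnation-triggered restart: for each individual whose personal
    best has not improved for lm iterations, try a parent-child
    transformation at one node for each recorded parent, followed by the
    chemotaxis passes, keeping only strict improvements."""
    space = ctx.global_space()
    for ind in subgroup:
        if ind.stagnation < ctx.lm:
            continue
        node = int(ctx.rng.integers(ctx.score.n))
        recorded = parents(ind.g, node)
        if not recorded:
            continue
        best_g, best_fit = ind.g.copy(), ind.fitness
        for p in recorded:
            trial = Individual(g=best_g.copy(), fitness=best_fit)
            if trial.g[p, node]:
                trial.g[p, node] = False
                if creates_cycle(trial.g, node, p):
                    trial.g[p, node] = True
                else:
                    trial.g[p, node] = True
                    _apply(trial, ctx, "reverse", p, node)
            _chemotaxis_passes(trial, ctx, node, space)
            if trial.fitness > best_fit:
                best_g, best_fit = trial.g, trial.fitness
        ind.g, ind.fitness = best_g, best_fit
        ind.stagnation = 0


def op_moth_flame(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """Personal bests are randomly permuted as flames; moth i learns
    toward flame i with the standard adoption rule."""
    flames = [subgroup[int(idx)].pbest_g.copy() for idx in ctx.rng.permutation(len(subgroup))]
    for ind, flame in zip(subgroup, flames):
        _adopt_differences(ind, flame, ctx, ctx.c)


def op_tlbo_learner(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """Each learner is paired with a random collaborator and adopts its
    differences only when the collaborator scores strictly higher."""
    k = len(subgroup)
    if k < 2:
        return
    for idx, ind in enumerate(subgroup):
        other = int(ctx.rng.integers(k - 1))
        if other >= idx:
            other += 1
        mate = subgroup[other]
        if mate.fitness > ind.fitness:
            _adopt_differences(ind, mate.g.copy(), ctx, ctx.c)


def force_prior_edges(ind: Individual, ctx: OperatorContext) -> None:
    """Insert every prior collider edge into one individual, deleting
    opposing edges; a cycle blocking an insertion is broken at the cycle
    edge whose removal costs the least fitness."""
    for p, c in sorted(ctx.priors.edges):
        if ind.g[c, p]:
            _apply(ind, ctx, "delete", c, p)
        if ind.g[p, c]:
            continue
        while creates_cycle(ind.g, p, c):
            path = _directed_path(ind.g, c, p)
            best_edge, best_delta = None, -math.inf
            for u, v in path:
                d = ctx.score.delta_delete(ind.g, u, v)
                if d > best_delta:
                    best_edge, best_delta = (u, v), d
            _apply(ind, ctx, "delete", *best_edge)
        _apply(ind, ctx, "add", p, c)


def _directed_path(g: np.ndarray, src: int, dst: int) -> list[tuple[int, int]]:
    """Edges of one directed path src -> ... -> dst (BFS)."""
    n = g.shape[0]
    prev = np.full(n, -1)
    prev[src] = src
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(g[u] & (prev == -1)).tolist():
                prev[v] = u
                if v == dst:
                    frontier = []
                    nxt = []
                    break
                nxt.append(v)
            else:
                continue
            break
        frontier = nxt
    if prev[dst] == -1:
        raise RuntimeError("no path found while breaking a cycle")
    path = []
    v = dst
    while v != src:
        path.append((int(prev[v]), v))
        v = int(prev[v])
    return path[::-1]


def op_expert_knowledge(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """A random ceil(zj * size) subset of individuals receives every
    v-structure prior edge."""
    if not ctx.priors.edges:
        return
    count = math.ceil(ctx.zj * len(subgroup))
    picks = ctx.rng.choice(len(subgroup), size=count, replace=False)
    for idx in picks.tolist():
        force_prior_edges(subgroup[idx], ctx)


def op_pruning(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """Remove every edge contributing less than mu = ln m to the score
    (guards against overfitting at small sample sizes)."""
    mu = ctx.mu
    for ind in subgroup:
        for i, j in [tuple(e) for e in np.argwhere(ind.g)]:
            contribution = -ctx.score.delta_delete(ind.g, int(i), int(j))
            if contribution < mu:
                _apply(ind, ctx, "delete", int(i), int(j))


def op_neighborhood_perturbation(subgroup: list[Individual], ctx: OperatorContext) -> None:
    """A burst of 1-3 random moves per individual confined to the LSS,
    accepted unconditionally."""
    space = ctx.lss_space()
    for ind in subgroup:
        burst = int(ctx.rng.integers(1, 4))
        for _ in range(burst):
            move = _propose_random_move(ind, ctx, space)
            if move is not None:
                _apply(ind, ctx, *move)


#: registry consumed by the engine; order fixes operator ids
OPERATORS: dict[str, callable] = {
    "mutation": op_mutation,
    "cognitive_personal": op_cognitive_personal,
    "cooperative_global": op_cooperative_global,
    "chemotactic": op_chemotactic,
    "elimination_dispersal": op_elimination_dispersal,
    "worker_bees": op_worker_bees,
    "onlooker_bees": op_onlooker_bees,
    "scout_bees": op_scout_bees,
    "moth_flame": op_moth_flame,
    "tlbo_learner": op_tlbo_learner,
    "expert_knowledge": op_expert_knowledge,
    "pruning": op_pruning,
    "neighborhood_perturbation": op_neighborhood_perturbation,
}
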