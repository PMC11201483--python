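"""Operator library: shared invariants plus per-operator behaviour."""

import math

import numpy as np
import pytest

from causalhh.llh_library import (
    OPERATORS,
    Individual,
    OperatorContext,
    op_chemotactic,
    op_cognitive_personal,
    op_elimination_dispersal,
    op_expert_knowledge,
    op_moth_flame,
    op_mutation,
    op_neighborhood_perturbation,
    op_onlooker_bees,
    op_pruning,
    op_scout_bees,
    op_tlbo_learner,
    op_worker_bees,
)
from causalhh.model_core import SearchSpaces, UndirectedGraph, VStructurePrior, is_acyclic
from causalhh.partial_correlation import CITester
from causalhh.scoring import ScoreContext
from causalhh.sem_simulator import random_dag, sample_weights, simulate
from causalhh.sppc import run_sppc


def make_context(seed=0, n=8, m=400, k=0.01, priors=None, spaces=None):
    rng = np.random.default_rng(seed)
    adj = random_dag(n, 2.0, rng)
    data = simulate(sample_weights(adj, 1, rng), adj, m, rng)
    sppc = run_sppc(data, k)
    tester = CITester.from_data(data, k)
    ctx = OperatorContext(
        spaces=spaces or sppc.spaces,
        score=ScoreContext(data),
        priors=priors if priors is not None else sppc.priors,
        rng=np.random.default_rng(seed + 1),
        full_partials_abs=np.abs(tester.full_partials()),
        Lmax=2 * n,
    )
    return ctx, adj, data


def make_subgroup(ctx, size=6, seed=2):
    rng = np.random.default_rng(seed)
    subgroup = []
    gss = ctx.spaces.gss.adjacency
    for _ in range(size):
        g = np.zeros((ctx.score.n, ctx.score.n), dtype=bool)
        for i, j in np.argwhere(np.triu(gss, 1)).tolist():
            if rng.random() < 0.3:
                if rng.random() < 0.5:
                    i, j = j, i
                from causalhh.model_core import creates_cycle

                if not creates_cycle(g, i, j):
                    g[i, j] = True
        subgroup.append(Individual(g=g, fitness=ctx.score.graph_score(g)))
    ctx.subgroup_best = max(subgroup, key=lambda ind: ind.fitness)
    return subgroup


def assert_invariants(subgroup, ctx, space=None):
    """Post-operator contract: acyclic graphs, space confinement,
    fitness fields equal to a fresh score."""
    for ind in subgroup:
        assert is_acyclic(ind.g)
        assert ind.fitness == pytest.approx(ctx.score.graph_score(ind.g), abs=1e-8)
        if space is not None:
            for i, j in np.argwhere(ind.g).tolist():
                assert space[i, j]


@pytest.mark.parametrize("name", sorted(OPERATORS))
def test_operator_preserves_core_invariants(name):
    ctx, _, _ = make_context(seed=3)
    subgroup = make_subgroup(ctx)
    ctx.c = 0.3
    OPERATORS[name](subgroup, ctx)
    assert_invariants(subgroup, ctx)


def test_registry_exposes_exactly_13_operators():
    assert len(OPERATORS) == 13


class TestMutation:
    def test_proposals_stay_in_global_space(self):
        ctx, _, _ = make_context(seed=4)
        allowed = ctx.global_space()
        for trial in range(20):
            subgroup = make_subgroup(ctx, seed=trial)
            op_mutation(subgroup, ctx)
            assert_invariants(subgroup, ctx, space=allowed | allowed.T)

    def test_css_switch_widens_proposals(self):
        ctx, _, _ = make_context(seed=5)
        ctx.spaces.css_active = True
        n = ctx.score.n
        assert ctx.global_space().sum() == n * n - n


class TestLearningOperators:
    def test_cognitive_noop_at_pbest_or_zero_c(self):
        ctx, _, _ = make_context(seed=6)
        subgroup = make_subgroup(ctx)
        snapshots = [ind.g.copy() for ind in subgroup]
        ctx.c = 0.0
        op_cognitive_personal(subgroup, ctx)
        for ind, snap in zip(subgroup, snapshots):
            assert np.array_equal(ind.g, snap)

    def test_cognitive_contracts_toward_pbest(self):
        from causalhh.model_core import hamming_distance

        ctx, _, _ = make_context(seed=7)
        subgroup = make_subgroup(ctx)
        target = subgroup[0].pbest_g
        ctx.c = 0.5
        before = hamming_distance(subgroup[0].g, target)
        dists = []
        for _ in range(30):
            op_cognitive_personal([subgroup[0]], ctx)
            dists.append(hamming_distance(subgroup[0].g, target))
        assert min(dists) <= before

    def test_tlbo_uniform_fitness_is_noop(self):
        ctx, _, _ = make_context(seed=8)
        subgroup = make_subgroup(ctx)
        for ind in subgroup:
            ind.g = subgroup[0].g.copy()
            ind.fitness = subgroup[0].fitness
        snapshots = [ind.g.copy() for ind in subgroup]
        ctx.c = 1.0
        op_tlbo_learner(subgroup, ctx)
        for ind, snap in zip(subgroup, snapshots):
            assert np.array_equal(ind.g, snap)

    def test_moth_flame_identical_pbests_acts_like_cognitive(self):
        ctx, _, _ = make_context(seed=9)
        subgroup = make_subgroup(ctx)
        shared = subgroup[0].pbest_g.copy()
        for ind in subgroup:
            ind.pbest_g = shared.copy()
        ctx.c = 1.0
        op_moth_flame(subgroup, ctx)
        assert_invariants(subgroup, ctx)


class TestBeeOperators:
    def test_worker_never_decreases_fitness(self):
        ctx, _, _ = make_context(seed=10)
        for trial in range(10):
            subgroup = make_subgroup(ctx, seed=100 + trial)
            before = [ind.fitness for ind in subgroup]
            op_worker_bees(subgroup, ctx)
            for ind, b in zip(subgroup, before):
                assert ind.fitness >= b - 1e-12

    def test_onlooker_prefers_higher_ranks(self):
        ctx, _, _ = make_context(seed=11)
        subgroup = make_subgroup(ctx, size=5)
        # spy on the rank-proportional draw through the rng stream
        counts = np.zeros(5)
        ranks = np.argsort(np.argsort([ind.fitness for ind in subgroup])) + 1
        probs = ranks / ranks.sum()
        draws = ctx.rng.choice(5, size=10_000, p=probs)
        counts += np.bincount(draws, minlength=5)
        freq = counts / counts.sum()
        assert np.allclose(freq, probs, atol=0.02)

    def test_scout_noop_below_stagnation_threshold(self):
        ctx, _, _ = make_context(seed=12)
        subgroup = make_subgroup(ctx)
        for ind in subgroup:
            ind.stagnation = 0
        snapshots = [ind.g.copy() for ind in subgroup]
        op_scout_bees(subgroup, ctx)
        for ind, snap in zip(subgroup, snapshots):
            assert np.array_equal(ind.g, snap)

    def test_scout_never_scores_below_entry(self):
        ctx, _, _ = make_context(seed=13)
        for trial in range(10):
            subgroup = make_subgroup(ctx, seed=200 + trial)
            for ind in subgroup:
                ind.stagnation = ctx.lm
            before = [ind.fitness for ind in subgroup]
            op_scout_bees(subgroup, ctx)
            for ind, b in zip(subgroup, before):
                assert ind.fitness >= b - 1e-12
                assert ind.stagnation in (0, ctx.lm)  # reset only when parents existed


class TestChemotacticAndRestart:
    def test_adds_strong_parent_on_noiseless_data(self):
        from causalhh.model_core import DataMatrix

        rng = np.random.default_rng(14)
        x = rng.standard_normal(500)
        dm = DataMatrix(np.column_stack([x, 2.0 * x + 0.01 * rng.standard_normal(500)]), names=["x", "y"])
        gss = UndirectedGraph.empty(2)
        gss.add_edge(0, 1)
        spaces = SearchSpaces(gss=gss, lss=gss.copy())
        ctx = OperatorContext(
            spaces=spaces,
            score=ScoreContext(dm),
            priors=VStructurePrior(),
            rng=np.random.default_rng(0),
            full_partials_abs=np.ones((2, 2)),
        )
        ind = Individual(g=np.zeros((2, 2), bool), fitness=ctx.score.graph_score(np.zeros((2, 2), bool)))
        from causalhh.llh_library import _chemotaxis_passes

        _chemotaxis_passes(ind, ctx, 1, gss.adjacency)
        assert ind.g[0, 1]

    def test_restart_fire_probability_schedule(self):
        ctx, _, _ = make_context(seed=15)
        ctx.L = 0
        assert ctx.c3 == pytest.approx(0.1)
        ctx.L = ctx.Lmax
        assert ctx.c3 == pytest.approx(1.0)

    def test_restart_monotone_from_stripped_start(self):
        ctx, _, _ = make_context(seed=16)
        ctx.L = ctx.Lmax  # always fire
        for trial in range(10):
            subgroup = make_subgroup(ctx, seed=300 + trial)
            ctx.subgroup_best = max(subgroup, key=lambda ind: ind.fitness)
            op_elimination_dispersal(subgroup, ctx)
            assert_invariants(subgroup, ctx)


class TestPriorAndCleanupOperators:
    def test_expert_knowledge_touches_exact_fraction_and_enforces_prior(self):
        priors = VStructurePrior(edges={(0, 2), (1, 2)})
        ctx, _, _ = make_context(seed=17, priors=priors)
        subgroup = make_subgroup(ctx, size=10)
        op_expert_knowledge(subgroup, ctx)
        holders = [
            ind for ind in subgroup if all(ind.g[p, c] for p, c in priors.edges)
        ]
        assert len(holders) >= math.ceil(0.5 * len(subgroup))
        assert_invariants(subgroup, ctx)

    def test_expert_knowledge_empty_prior_is_noop(self):
        ctx, _, _ = make_context(seed=18, priors=VStructurePrior())
        subgroup = make_subgroup(ctx)
        snapshots = [ind.g.copy() for ind in subgroup]
        op_expert_knowledge(subgroup, ctx)
        for ind, snap in zip(subgroup, snapshots):
            assert np.array_equal(ind.g, snap)

    def test_pruning_removes_weak_edges_keeps_strong(self):
        ctx, adj, data = make_context(seed=19, n=8, m=1000)
        assert ctx.mu == pytest.approx(math.log(1000))
        ind = Individual(g=adj.copy(), fitness=ctx.score.graph_score(adj))
        op_pruning([ind], ctx)
        # unit-weight edges contribute ~ m/2 x variance drop >> ln m
        assert ind.g.sum() >= 0.8 * adj.sum()
        for i, j in np.argwhere(ind.g).tolist():
            assert -ctx.score.delta_delete(ind.g, i, j) >= ctx.mu

    def test_perturbation_confined_to_lss(self):
        ctx, _, _ = make_context(seed=20)
        lss = ctx.lss_space()
        for trial in range(10):
            subgroup = make_subgroup(ctx, seed=400 + trial)
            before = [ind.g.copy() for ind in subgroup]
            op_neighborhood_perturbation(subgroup, ctx)
            for ind, b in zip(subgroup, before):
                # every genuinely new adjacency (not a reversal of an
                # existing edge) must be an LSS member
                new_pairs = np.argwhere((ind.g | ind.g.T) & ~(b | b.T))
                for i, j in new_pairs.tolist():
                    assert lss[i, j]
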