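"""Shared fixtures: small SEM instances and graph enumeration helpers."""

import itertools

import numpy as np
import pytest

from causalhh.model_core import DataMatrix, is_acyclic
from causalhh.sem_simulator import SemSpec, analytic_covariance, simulate


def collider_adjacency() -> np.ndarray:
    """x -> z <- y on nodes (x, y, z) = (0, 1, 2), unit weights."""
    adj = np.zeros((3, 3), dtype=bool)
    adj[0, 2] = adj[1, 2] = True
    return adj


def chain_adjacency() -> np.ndarray:
    """x -> y -> z on nodes (0, 1, 2), unit weights."""
    adj = np.zeros((3, 3), dtype=bool)
    adj[0, 1] = adj[1, 2] = True
    return adj


def unit_spec(adj: np.ndarray) -> SemSpec:
    return SemSpec(sem_id=1, weights=np.where(adj, 1.0, 0.0))


@pytest.fixture(scope="session")
def collider_data() -> DataMatrix:
    adj = collider_adjacency()
    rng = np.random.default_rng(42)
    return simulate(unit_spec(adj), adj, 5000, rng, names=["x", "y", "z"])


@pytest.fixture(scope="session")
def chain_data() -> DataMatrix:
    adj = chain_adjacency()
    rng = np.random.default_rng(43)
    return simulate(unit_spec(adj), adj, 5000, rng, names=["x", "y", "z"])


@pytest.fixture(scope="session")
def collider_sigma() -> np.ndarray:
    return analytic_covariance(unit_spec(collider_adjacency()), collider_adjacency())


@pytest.fixture(scope="session")
def chain_sigma() -> np.ndarray:
    return analytic_covariance(unit_spec(chain_adjacency()), chain_adjacency())


def all_dags(n: int):
    """Every labelled DAG on n nodes (543 for n = 4)."""
    cells = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in itertools.product((0, 1), repeat=len(cells)):
        a = np.zeros((n, n), dtype=bool)
        for b, (i, j) in zip(bits, cells):
            if b:
                a[i, j] = True
        if is_acyclic(a):
            yield a


def random_digraph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = rng.random((n, n)) < p
    np.fill_diagonal(a, False)
    return a
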