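"""Shared domain types and graph primitives.

Graphs are plain boolean numpy adjacency matrices throughout: entry
``(i, j)`` of a directed adjacency means the edge ``i -> j``; undirected
graphs keep the matrix symmetric.  Parent and neighbour sets are derived
views, never stored redundantly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np


class StructuralError(ValueError):
    """Malformed graph or data input (shape, symmetry, cycles)."""


class DegenerateInputError(ValueError):
    """Numerically degenerate data, e.g. a zero-variance column."""


@dataclass
class DataMatrix:
    """An ``m x n`` matrix of continuous observations.

    Columns are mean-centered at construction: the OLS regressions used by
    the score have no intercept term, so centering makes them well-posed
    while leaving all correlations unchanged.
    """

    values: np.ndarray
    names: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StructuralError("data must be a 2-D matrix")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise StructuralError(f"need at least 2 samples and 2 variables, got {m}x{n}")
        if len(self.names) != n:
            raise StructuralError(f"{len(self.names)} names for {n} columns")
        if not np.all(np.isfinite(self.values)):
            raise DegenerateInputError("data contains missing or non-finite values")
        self.values = self.values - self.values.mean(axis=0)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def index_of(self, name: str) -> int:
        try:
            return list(self.names).index(name)
        except ValueError:
            raise KeyError(f"unknown variable name: {name!r}") from None


@dataclass
class UndirectedGraph:
    """Symmetric boolean adjacency; used for the Markov random field and
    the global/local search spaces."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise StructuralError("adjacency must be square")
        if np.any(np.diag(a)):
            raise StructuralError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise StructuralError("undirected adjacency must be symmetric")
        self.adjacency = a

    @classmethod
    def empty(cls, n: int) -> "UndirectedGraph":
        return cls(np.zeros((n, n), dtype=bool))

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adjacency[i, j])

    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise StructuralError("self-loop")
        self.adjacency[i, j] = self.adjacency[j, i] = True

    def remove_edge(self, i: int, j: int) -> None:
        self.adjacency[i, j] = self.adjacency[j, i] = False

    def edges(self) -> Iterator[tuple[int, int]]:
        """Unordered edges as (i, j) with i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        return zip(iu.tolist(), ju.tolist())

    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2

    def copy(self) -> "UndirectedGraph":
        return UndirectedGraph(self.adjacency.copy())


def is_acyclic(adjacency: np.ndarray) -> bool:
    """True iff the directed adjacency admits a topological order.

    Kahn's algorithm on the boolean matrix; vectorised in-degree updates.
    """
    a = np.asarray(adjacency, dtype=bool)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise StructuralError("adjacency must be square")
    n = a.shape[0]
    work = a.copy()
    alive = np.ones(n, dtype=bool)
    for _ in range(n):
        indeg = work.sum(axis=0)
        roots = alive & (indeg == 0)
        if not roots.any():
            return not alive.any()
        work[roots, :] = False
        alive &= ~roots
    return not alive.any()


def topological_order(adjacency: np.ndarray) -> list[int]:
    """A topological order of the DAG; raises if the graph is cyclic."""
    a = np.asarray(adjacency, dtype=bool)
    n = a.shape[0]
    work = a.copy()
    alive = np.ones(n, dtype=bool)
    order: list[int] = []
    while alive.any():
        indeg = work.sum(axis=0)
        roots = np.flatnonzero(alive & (indeg == 0))
        if roots.size == 0:
            raise StructuralError("graph contains a directed cycle")
        for r in roots.tolist():
            order.append(r)
        work[roots, :] = False
        alive[roots] = False
    return order


def creates_cycle(adjacency: np.ndarray, i: int, j: int) -> bool:
    """Would adding the edge i -> j close a directed cycle?

    True iff j already reaches i; breadth-first search over successors.
    """
    if i == j:
        return True
    a = adjacency
    n = a.shape[0]
    seen = np.zeros(n, dtype=bool)
    frontier = np.zeros(n, dtype=bool)
    frontier[j] = True
    while frontier.any():
        if frontier[i]:
            return True
        seen |= frontier
        frontier = a[frontier].any(axis=0) & ~seen
    return False


def hamming_distance(g1: np.ndarray, g2: np.ndarray) -> int:
    """Number of ordered adjacency cells on which the two graphs differ."""
    a1 = np.asarray(g1, dtype=bool)
    a2 = np.asarray(g2, dtype=bool)
    if a1.shape != a2.shape:
        raise StructuralError(f"dimension mismatch: {a1.shape} vs {a2.shape}")
    return int(np.sum(a1 != a2))


def parents(adjacency: np.ndarray, j: int) -> tuple[int, ...]:
    """pa(j) as a sorted tuple (cache-key friendly)."""
    return tuple(np.flatnonzero(adjacency[:, j]).tolist())


@dataclass
class SepSetRecord:
    """Outcome of the greedy d-separating-set search for one pair."""

    i: int
    j: int
    found: bool
    Z: frozenset[int]
    removed: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise StructuralError("a pair needs two distinct variables")
        if self.i in self.Z or self.j in self.Z:
            raise StructuralError("separating set may not contain the pair itself")
        if set(self.removed) & set(self.Z):
            raise StructuralError("removed nodes cannot remain in the separating set")


@dataclass
class VStructurePrior:
    """Directed collider edges (parent -> collider) mined by the
    constraint phase; used to seed and guide the score search."""

    edges: set[tuple[int, int]] = field(default_factory=set)

    def colliders(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for p, c in self.edges:
            out.setdefault(c, set()).add(p)
        return out

    def as_adjacency(self, n: int) -> np.ndarray:
        a = np.zeros((n, n), dtype=bool)
        for p, c in self.edges:
            a[p, c] = True
        return a

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class SearchSpaces:
    """Nested edge sets restricting operator proposals.

    ``gss`` (global) is the full partial-correlation graph; ``lss``
    (local) drops the edges explained away as v-structure artefacts.  The
    complete space (CSS) is implicit: once ``css_active`` is set the
    global operators may propose any pair.
    """

    gss: UndirectedGraph
    lss: UndirectedGraph
    css_active: bool = False

    def __post_init__(self) -> None:
        if np.any(self.lss.adjacency & ~self.gss.adjacency):
            raise StructuralError("LSS must be a subgraph of GSS")

    def global_allows(self, i: int, j: int) -> bool:
        return self.css_active or self.gss.has_edge(i, j)
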