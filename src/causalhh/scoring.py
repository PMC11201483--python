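"""Decomposable BIC fitness under ordinary-least-squares estimation.

Each node contributes

    score_j = -(nll_factor * RSS_j + |pa(j)|/2 * ln m)

where RSS_j is the residual sum of squares of regressing the (centered)
column j on its parent columns without intercept, and the default
``nll_factor = 0.5`` is the unit-variance Gaussian negative log-likelihood
up to constants.  The graph score is the sum over nodes; higher is better.

All regressions go through the precomputed Gram matrix S = X'X, so a fit
with p parents costs O(p^3) independent of the sample size, and results
are cached per (node, parent set).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from causalhh.model_core import DataMatrix, StructuralError, is_acyclic, parents

logger = logging.getLogger(__name__)

RIDGE = 1e-10


@dataclass(frozen=True)
class NodeScoreEntry:
    node: int
    parents: tuple[int, ...]
    theta: np.ndarray
    rss: float
    score: float


class ScoreContext:
    """Scoring service bound to one dataset.

    Holds the Gram matrix, the sample size, the ``nll_factor`` switch
    (0.5 default; 1.0 scores the raw RSS) and the per-node cache.
    """

    def __init__(self, data: DataMatrix, nll_factor: float = 0.5):
        self.data = data
        self.m = data.m
        self.n = data.n
        self.nll_factor = float(nll_factor)
        self.log_m = math.log(self.m)
        self.gram = data.values.T @ data.values
        self._cache: dict[tuple[int, tuple[int, ...]], NodeScoreEntry] = {}
        self.hits = 0
        self.misses = 0

    def ols_fit(self, j: int, parent_set: Iterable[int]) -> tuple[np.ndarray, float]:
        """theta = (X'X)^-1 X'x_j over the parent columns, and the RSS.

        Empty parent set: theta is empty and RSS = sum x_j^2.  Collinear
        parents fall back to a ridge solve with a warning.
        """
        P = tuple(parent_set)
        if not P:
            return np.empty(0), float(self.gram[j, j])
        idx = list(P)
        Spp = self.gram[np.ix_(idx, idx)]
        Spj = self.gram[idx, j]
        try:
            theta = np.linalg.solve(Spp, Spj)
        except np.linalg.LinAlgError:
            logger.warning("collinear parents %s for node %d; ridge fallback", P, j)
            theta = np.linalg.solve(Spp + RIDGE * np.eye(len(idx)), Spj)
        rss = float(self.gram[j, j] - Spj @ theta)
        return theta, max(rss, 0.0)

    def node_entry(self, j: int, parent_set: Iterable[int]) -> NodeScoreEntry:
        key = (j, tuple(sorted(parent_set)))
        entry = self._cache.get(key)
        if entry is not None:
            self.hits += 1
            return entry
        self.misses += 1
        theta, rss = self.ols_fit(j, key[1])
        score = -(self.nll_factor * rss + 0.5 * len(key[1]) * self.log_m)
        entry = NodeScoreEntry(node=j, parents=key[1], theta=theta, rss=rss, score=score)
        self._cache[key] = entry
        return entry

    def node_score(self, j: int, parent_set: Iterable[int]) -> float:
        return self.node_entry(j, parent_set).score

    def graph_score(self, adjacency: np.ndarray) -> float:
        if not is_acyclic(adjacency):
            raise StructuralError("graph_score requires an acyclic graph")
        return sum(self.node_score(j, parents(adjacency, j)) for j in range(self.n))

    # -- incremental deltas ------------------------------------------------

    def delta_add(self, adjacency: np.ndarray, i: int, j: int) -> float:
        """Score change of adding i -> j (caller guarantees legality)."""
        pa = parents(adjacency, j)
        return self.node_score(j, pa + (i,)) - self.node_score(j, pa)

    def delta_delete(self, adjacency: np.ndarray, i: int, j: int) -> float:
        pa = parents(adjacency, j)
        reduced = tuple(p for p in pa if p != i)
        return self.node_score(j, reduced) - self.node_score(j, pa)

    def delta_reverse(self, adjacency: np.ndarray, i: int, j: int) -> float:
        """i -> j becomes j -> i: delete at child j plus add at new child i."""
        return self.delta_delete(adjacency, i, j) + self.delta_add(adjacency, j, i)

    def delta_score(self, adjacency: np.ndarray, move: tuple[str, int, int]) -> float:
        """Delta of ('add'|'delete'|'reverse', i, j) applied to adjacency."""
        kind, i, j = move
        if kind == "add":
            if adjacency[i, j]:
                raise StructuralError(f"edge {i}->{j} already present")
            return self.delta_add(adjacency, i, j)
        if kind == "delete":
            if not adjacency[i, j]:
                raise StructuralError(f"edge {i}->{j} absent")
            return self.delta_delete(adjacency, i, j)
        if kind == "reverse":
            if not adjacency[i, j]:
                raise StructuralError(f"edge {i}->{j} absent")
            return self.delta_reverse(adjacency, i, j)
        raise StructuralError(f"unknown move kind {kind!r}")

    def cache_info(self) -> tuple[int, int]:
        return self.hits, self.misses
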