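"""Linear SEM ground-truth generation and sampling.

Three generating mechanisms over a weighted DAG, differing in the weight
and disturbance laws:

    SEM 1:  x_i = w1' pa(x_i) + N(0, 1)        w1 = +-1 + N(0,1)/4
    SEM 2:  x_i = w2' pa(x_i) + N(0, 1)        w2 ~ Uniform(0.2, 1)
    SEM 3:  x_i = w1' pa(x_i) + Uniform(-1, 1)

SEMs 1 and 2 are linear-Gaussian; SEM 3 is linear non-Gaussian.  Weights
are drawn once per dataset.  The module also provides the closed-form
population covariance, which serves as an analytic oracle for the CI-test
and constraint-phase property suites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from causalhh.model_core import DataMatrix, StructuralError, topological_order


@dataclass(frozen=True)
class SemSpec:
    """One sampled parameterisation: mechanism id, weight matrix (entry
    (i, j) is the coefficient of parent i in child j's equation), and the
    per-node noise variance implied by the mechanism."""

    sem_id: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.sem_id not in (1, 2, 3):
            raise StructuralError(f"unknown SEM id {self.sem_id}")

    @property
    def noise_variance(self) -> float:
        # Uniform(-1, 1) has variance 1/3; the Gaussian disturbances are standard
        return 1.0 / 3.0 if self.sem_id == 3 else 1.0


def random_dag(n: int, avg_degree: float, rng: np.random.Generator) -> np.ndarray:
    """Random DAG: uniform topological order, each forward pair included
    independently with probability avg_degree / (n - 1)."""
    if n < 2:
        raise StructuralError("need at least 2 nodes")
    if avg_degree >= n:
        raise StructuralError("average degree must be below n - 1")
    order = rng.permutation(n)
    p = avg_degree / (n - 1)
    adj = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p:
                adj[order[a], order[b]] = True
    return adj


def sample_weights(adjacency: np.ndarray, sem_id: int, rng: np.random.Generator) -> SemSpec:
    """Draw one weight per edge from the mechanism's law; non-edges are 0."""
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    W = np.zeros((n, n))
    idx = np.nonzero(adj)
    ne = idx[0].size
    if sem_id in (1, 3):
        signs = rng.choice([-1.0, 1.0], size=ne)
        W[idx] = signs + rng.standard_normal(ne) / 4.0
    elif sem_id == 2:
        W[idx] = rng.uniform(0.2, 1.0, size=ne)
    else:
        raise StructuralError(f"unknown SEM id {sem_id}")
    return SemSpec(sem_id=sem_id, weights=W)


def simulate(
    spec: SemSpec,
    adjacency: np.ndarray,
    m: int,
    rng: np.random.Generator,
    names: list[str] | None = None,
) -> DataMatrix:
    """Sample m observations in topological order; columns are centered
    by the DataMatrix constructor."""
    if m < 2:
        raise StructuralError("need at least 2 samples")
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    X = np.zeros((m, n))
    if spec.sem_id == 3:
        noise = rng.uniform(-1.0, 1.0, size=(m, n))
    else:
        noise = rng.standard_normal((m, n))
    for j in topological_order(adj):
        pa = np.flatnonzero(adj[:, j])
        X[:, j] = noise[:, j]
        if pa.size:
            X[:, j] += X[:, pa] @ spec.weights[pa, j]
    if names is None:
        names = [f"X{i}" for i in range(n)]
    return DataMatrix(values=X, names=names)


def analytic_covariance(spec: SemSpec, adjacency: np.ndarray) -> np.ndarray:
    """Population covariance Sigma = (I - W)^-T D (I - W)^-1 with
    D = diag(noise variances); W aligned parent-row/child-column."""
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    W = np.where(adj, spec.weights, 0.0)
    A = np.linalg.inv(np.eye(n) - W)  # (I - W)^-1
    return spec.noise_variance * (A.T @ A)
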