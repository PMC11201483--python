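"""Partial correlations and the Bayes-factor conditional-independence test.

For data generated by a linear SEM with homoscedastic uncorrelated noise,
a vanishing partial correlation rho_{ij|Z} is equivalent to conditional
independence, so thresholding a significance measure of rho gives a CI
test.  The test statistic

    t = rho / sqrt((1 - rho^2) / (m - n))

approximately follows a t distribution with m - n degrees of freedom for
large samples (m: observations, n: variables).  Significance is judged by
the BIC-approximation Bayes factor of the independence hypothesis,

    BF01 = sqrt(m) * (1 + t^2 / (m - n))^(-m/2),

a strictly decreasing function of |t|; the pair is declared dependent
when BF01 falls below a threshold ``k`` (default 0.01).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from causalhh.model_core import DataMatrix, DegenerateInputError

logger = logging.getLogger(__name__)

#: ridge added to a singular correlation matrix before inversion
RIDGE = 1e-10


class NumericError(ArithmeticError):
    """Singular matrix that the ridge fallback could not rescue."""


class ConfigurationError(ValueError):
    """Invalid test configuration, e.g. m <= n."""


@dataclass(frozen=True)
class CorrTestResult:
    """One conditional-independence decision."""

    rho: float
    t: float
    bf01: float
    dependent: bool


def correlation_matrix(data: DataMatrix) -> np.ndarray:
    """Pearson correlation matrix of the columns.

    Raises on a zero-variance column, naming it: a constant variable has
    no defined correlation.
    """
    sd = data.values.std(axis=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        name = data.names[bad[0]]
        raise DegenerateInputError(f"column {name!r} has zero variance")
    R = np.corrcoef(data.values, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return R


def _invert(mat: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        logger.warning("singular correlation matrix; retrying with ridge %.0e", RIDGE)
        try:
            return np.linalg.inv(mat + RIDGE * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise NumericError(
                "correlation matrix is singular even after adding ridge "
                f"{RIDGE:.0e}; check for duplicated columns or m < n"
            ) from exc


def full_partial_matrix(R: np.ndarray) -> np.ndarray:
    """Matrix of full partial correlations rho_{ij | all others}.

    With P = R^-1 = (r_ij), the entry is -r_ij / sqrt(r_ii * r_jj).  The
    diagonal is meaningless and set to 1.
    """
    P = _invert(R)
    d = np.sqrt(np.abs(np.diag(P)))
    rho = -P / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def t_statistic(rho: float, m: int, n: int) -> float:
    """t = rho / sqrt((1 - rho^2) / (m - n)); signed infinity at |rho| = 1."""
    if m <= n:
        raise ConfigurationError(f"need m > n for the t approximation (m={m}, n={n})")
    if abs(rho) >= 1.0:
        return math.copysign(math.inf, rho)
    return rho / math.sqrt((1.0 - rho * rho) / (m - n))


def bayes_factor(t: float, m: int, n: int) -> float:
    """BF01 of independence vs. dependence given the t statistic.

    Closed form sqrt(m) * (1 + t^2/(m-n))^(-m/2), evaluated in log space
    to avoid underflow at large |t|.  Strictly decreasing in |t| and equal
    to sqrt(m) at t = 0.
    """
    if m <= n:
        raise ConfigurationError(f"need m > n (m={m}, n={n})")
    if math.isinf(t):
        return 0.0
    log_bf = 0.5 * math.log(m) - 0.5 * m * math.log1p(t * t / (m - n))
    return math.exp(log_bf)


class CITester:
    """Conditional-independence testing against one correlation matrix.

    Built either from a :class:`DataMatrix` (sample correlations, real m)
    or from a model covariance with a nominal sample size — the latter
    makes population-limit reasoning available to the constraint phase
    and to tests without drawing any data.
    """

    def __init__(self, R: np.ndarray, m: int, k: float = 0.01):
        R = np.asarray(R, dtype=float)
        n = R.shape[0]
        if m <= n:
            raise ConfigurationError(
                f"sample size m={m} must exceed the variable count n={n}; "
                "collect more samples or screen variables first"
            )
        self.R = R
        self.m = int(m)
        self.n = n
        self.k = float(k)
        self.tests_run = 0

    @classmethod
    def from_data(cls, data: DataMatrix, k: float = 0.01) -> "CITester":
        return cls(correlation_matrix(data), data.m, k)

    @classmethod
    def from_covariance(cls, sigma: np.ndarray, m: int, k: float = 0.01) -> "CITester":
        sigma = np.asarray(sigma, dtype=float)
        d = np.sqrt(np.diag(sigma))
        return cls(sigma / np.outer(d, d), m, k)

    def partial_correlation(self, i: int, j: int, Z: Iterable[int]) -> float:
        """rho_{ij|Z} by inversion of the sub-correlation matrix over
        {i, j} u Z (equals the residual-correlation definition)."""
        Zt = tuple(Z)
        if i == j or i in Zt or j in Zt:
            raise ConfigurationError("conditioning set must exclude the tested pair")
        if not Zt:
            return float(self.R[i, j])
        idx = [i, j, *Zt]
        P = _invert(self.R[np.ix_(idx, idx)])
        rho = -P[0, 1] / math.sqrt(abs(P[0, 0] * P[1, 1]))
        return float(np.clip(rho, -1.0, 1.0))

    def full_partials(self) -> np.ndarray:
        return full_partial_matrix(self.R)

    def decide(self, rho: float) -> CorrTestResult:
        t = t_statistic(rho, self.m, self.n)
        bf = bayes_factor(t, self.m, self.n)
        # strict inequality: ties at bf01 == k resolve to independence
        return CorrTestResult(rho=rho, t=t, bf01=bf, dependent=bf < self.k)

    def ci_decision(self, i: int, j: int, Z: Iterable[int] = ()) -> CorrTestResult:
        self.tests_run += 1
        return self.decide(self.partial_correlation(i, j, Z))

    def dependent(self, i: int, j: int, Z: Iterable[int] = ()) -> bool:
        return self.ci_decision(i, j, Z).dependent


def local_partial(data: DataMatrix, i: int, j: int, Z: Iterable[int]) -> float:
    """rho_{ij|Z} for a data matrix (convenience over :class:`CITester`)."""
    return CITester.from_data(data).partial_correlation(i, j, Z)


def ci_decision(
    data: DataMatrix, i: int, j: int, Z: Iterable[int] = (), k: float = 0.01
) -> CorrTestResult:
    """One-shot CI decision on a data matrix."""
    return CITester.from_data(data, k).ci_decision(i, j, Z)
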