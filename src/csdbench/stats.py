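"""Gaussian sufficient statistics: Fisher-z CI test and decomposable BIC."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graphs import MixedGraph

__all__ = [
    "CovarianceModel",
    "IndependenceResult",
    "ScoreConfig",
    "fisher_z_test",
    "partial_correlation",
    "local_bic_score",
    "graph_bic_score",
]


class StatError(ValueError):
    pass


@dataclass(frozen=True)
class CovarianceModel:
    """Covariance matrix + sample size: the sufficient statistic for every
    Gaussian computation in the package."""

    names: tuple[str, ...]
    matrix: np.ndarray
    n: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.names), len(self.names)):
            raise StatError("covariance shape does not match variable names")
        if not np.allclose(m, m.T, atol=1e-10):
            raise StatError("covariance matrix is not symmetric")
        object.__setattr__(self, "matrix", (m + m.T) / 2.0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CovarianceModel":
        """ML (ddof=0) covariance of the numeric columns."""
        data = df.to_numpy(dtype=float)
        cov = np.cov(data, rowvar=False, ddof=0)
        cov = np.atleast_2d(cov)
        return cls(tuple(df.columns), cov, len(df))

    def index(self, name: str) -> int:
        return self.names.index(name)

    def submatrix(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.index(v) for v in names]
        return self.matrix[np.ix_(idx, idx)]


@dataclass(frozen=True)
class IndependenceResult:
    x: str
    y: str
    conditioning: tuple[str, ...]
    r: float
    z: float
    p_value: float
    alpha: float

    @property
    def independent(self) -> bool:
        return self.p_value > self.alpha

    @property
    def s(self) -> int:
        return len(self.conditioning)


@dataclass(frozen=True)
class ScoreConfig:
    """BIC penalty weight; score = -n ln(sigma^2) - c (k+1) ln(n)."""

    penalty_discount: float = 1.0

    def __post_init__(self) -> None:
        if self.penalty_discount <= 0:
            raise StatError("penalty_discount must be positive")


def partial_correlation(cov: CovarianceModel, x: str, y: str,
                        conditioning: Iterable[str]) -> float:
    """Partial correlation of x, y given a conditioning set, from the
    inverse of the relevant covariance submatrix."""
    S = sorted(set(conditioning))
    if x == y or x in S or y in S:
        raise StatError("x, y must be distinct and outside the conditioning set")
    sub = cov.submatrix([x, y, *S])
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise StatError("singular conditioning submatrix") from exc
    r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    return float(np.clip(r, -1.0, 1.0))


def fisher_z_test(cov: CovarianceModel, x: str, y: str,
                  conditioning: Iterable[str] = (),
                  alpha: float = 0.05) -> IndependenceResult:
    """Two-sided Fisher-z test of zero partial correlation.

    z = arctanh(r) * sqrt(n - |S| - 3), referred to the standard normal.
    |r| is clamped at 1 - 1e-12 before the transform to avoid overflow.
    """
    S = tuple(sorted(set(conditioning)))
    if not 0 < alpha < 1:
        raise StatError("alpha must lie in (0, 1)")
    dof = cov.n - len(S) - 3
    if dof <= 0:
        raise StatError(f"degrees of freedom exhausted: n={cov.n}, |S|={len(S)}")
    r = partial_correlation(cov, x, y, S)
    r_c = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    z = float(np.arctanh(r_c) * np.sqrt(dof))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return IndependenceResult(x, y, S, r, z, p, alpha)


def _residual_variance(cov: CovarianceModel, child: str,
                       parents: Sequence[str]) -> float:
    i = cov.index(child)
    s_yy = cov.matrix[i, i]
    if not parents:
        return float(s_yy)
    pidx = [cov.index(p) for p in parents]
    s_xx = cov.matrix[np.ix_(pidx, pidx)]
    s_xy = cov.matrix[pidx, i]
    try:
        beta = np.linalg.solve(s_xx, s_xy)
    except np.linalg.LinAlgError as exc:
        raise StatError(f"collinear parents for {child}: {parents}") from exc
    return float(s_yy - s_xy @ beta)


def local_bic_score(cov: CovarianceModel, child: str,
                    parents: Iterable[str] = (),
                    config: ScoreConfig = ScoreConfig()) -> float:
    """Decomposable Gaussian BIC contribution of one node (higher = better):

        -n * ln(sigma^2_{child|parents}) - c * (|parents| + 1) * ln(n)

    with sigma^2 the ML residual variance of the child's regression.
    """
    parents = sorted(set(parents))
    if child in parents:
        raise StatError("child cannot be its own parent")
    n = cov.n
    sigma2 = _residual_variance(cov, child, parents)
    if sigma2 <= 0:
        sigma2 = 1e-300  # deterministic child; score saturates
    return float(-n * np.log(sigma2)
                 - config.penalty_discount * (len(parents) + 1) * np.log(n))


def graph_bic_score(cov: CovarianceModel, dag: MixedGraph,
                    config: ScoreConfig = ScoreConfig()) -> float:
    """Total BIC of a DAG: sum of local scores over all nodes."""
    if not dag.is_dag():
        raise StatError("graph_bic_score requires a DAG")
    return sum(local_bic_score(cov, v, dag.parents(v), config) for v in dag.nodes)
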