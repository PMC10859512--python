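"""Regularized partial-correlation network estimation.

The network is a Gaussian graphical model estimated from Spearman
correlations of the ordinal items: the graphical lasso is fit along a
logarithmically spaced penalty path and the extended Bayesian information
criterion (EBIC, hyperparameter gamma = 0.5 by default) picks the penalty,
yielding a sparse matrix of partial correlations
``w_ij = -K_ij / sqrt(K_ii * K_jj)`` whose nonzero entries are the edges.

Spearman correlations are used instead of polychoric because item scores
are ordinal and strongly skewed, where sparse cross-tables bias polychoric
estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .synthetic import ANXIETY, DEPRESSION, NODE_NAMES

#: |w| below this is counted as "no edge"; makes the edge count well defined
#: in floating point.
EDGE_ZERO_TOL = 1e-8


class EstimationError(RuntimeError):
    pass


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal item correlation matrix plus its sample size."""

    values: np.ndarray
    n: int
    node_names: tuple[str, ...] = NODE_NAMES

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(V), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        self.values = (V + V.T) / 2
        self.node_names = tuple(self.node_names)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


@dataclass
class NetworkModel:
    """Selected sparse partial-correlation network."""

    weights: np.ndarray
    node_names: tuple[str, ...]
    communities: tuple[str, ...]
    lambda_selected: float
    ebic_value: float
    n: int
    gamma: float
    #: (lambda, ebic, edge_count) for every converged path point
    path: list[tuple[float, float, int]] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def n_possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int((np.abs(self.weights[iu]) > 0).sum())

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0:
                    rows.append((self.node_names[i], self.node_names[j],
                                 float(w)))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


def infer_communities(node_names) -> tuple[str, ...]:
    """Instrument membership from item names (CESD* vs GAD*)."""
    out = []
    for name in node_names:
        if name.upper().startswith("CESD"):
            out.append(DEPRESSION)
        elif name.upper().startswith("GAD"):
            out.append(ANXIETY)
        else:
            raise ValueError(f"cannot infer community for node {name!r}")
    return tuple(out)


def spearman_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman correlations (average ranks for ties)."""
    X = np.asarray(table, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows for Spearman correlations")
    names = tuple(table.columns) if hasattr(table, "columns") else tuple(
        f"V{i+1}" for i in range(X.shape[1]))
    constant = [names[j] for j in range(X.shape[1])
                if np.all(X[:, j] == X[0, j])]
    if constant:
        raise ValueError(f"constant item(s), correlation undefined: {constant}")
    rho = spearmanr(X).statistic
    if X.shape[1] == 2:  # spearmanr returns a scalar for two columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    return CorrelationMatrix(np.asarray(rho), n=X.shape[0], node_names=names)


def repair_psd(corr: CorrelationMatrix,
               eig_floor: float = 1e-4) -> CorrelationMatrix:
    """Make a correlation matrix positive semidefinite if it is not.

    Spearman matrices computed pairwise on ordinal data need not be PSD,
    but the graphical lasso requires it.  Eigenvalues below ``eig_floor``
    are clipped, the matrix reconstructed and rescaled to unit diagonal;
    an already-PSD input is returned unchanged.
    """
    vals, vecs = np.linalg.eigh(corr.values)
    if vals[0] >= 0:
        return corr
    clipped = np.maximum(vals, eig_floor)
    R = (vecs * clipped) @ vecs.T
    d = 1.0 / np.sqrt(np.diag(R))
    R = d[:, None] * R * d[None, :]
    R = (R + R.T) / 2
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R, n=corr.n, node_names=corr.node_names)


def lambda_path(corr: CorrelationMatrix, n_points: int = 100,
                min_ratio: float = 0.01) -> np.ndarray:
    """Decreasing log-spaced penalty path from lambda_max down.

    ``lambda_max`` is the largest absolute off-diagonal correlation, at
    which the selected network is exactly empty.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    S = corr.values
    off = np.abs(S[np.triu_indices_from(S, k=1)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max == 0:
        warnings.warn("all off-diagonal correlations are zero; "
                      "degenerate single-point path at 0")
        return np.array([0.0])
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio),
                       n_points)


def graphical_lasso_fit(corr: CorrelationMatrix, lam: float,
                        tol: float = 1e-4, max_iter: int = 500) -> np.ndarray:
    """L1-penalized precision-matrix estimate at penalty ``lam``.

    Maximizes ``log det K - tr(S K) - lam * sum_{i != j} |K_ij|`` (the
    diagonal is unpenalized) by coordinate descent.  ``lam = 0`` returns
    the plain inverse of S.
    """
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    S = corr.values
    if lam == 0:
        try:
            return np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"singular correlation matrix: {exc}")
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            _, K = _sk_graphical_lasso(S, alpha=lam, tol=tol,
                                       max_iter=max_iter)
        except (FloatingPointError, ConvergenceWarning,
                np.linalg.LinAlgError) as exc:
            raise EstimationError(
                f"graphical lasso failed to converge at lambda={lam:.5g}: "
                f"{exc}")
    return (K + K.T) / 2


def precision_to_weights(K: np.ndarray) -> np.ndarray:
    """Partial correlations ``-K_ij / sqrt(K_ii K_jj)`` with zero diagonal."""
    K = np.asarray(K, dtype=float)
    d = 1.0 / np.sqrt(np.diag(K))
    W = -(d[:, None] * K * d[None, :])
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2


def ebic(K: np.ndarray, S: CorrelationMatrix | np.ndarray, n: int,
         gamma: float = 0.5, zero_tol: float = EDGE_ZERO_TOL) -> float:
    """Extended BIC of a precision matrix fit.

    ``-2 * (n/2) * (log det K - tr(S K)) + E log n + 4 E gamma log p`` where
    E counts off-diagonal pairs with ``|K_ij| > zero_tol``.  Constant
    likelihood terms are dropped; only EBIC differences matter for model
    selection.
    """
    Sv = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S)
    K = np.asarray(K, dtype=float)
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise EstimationError("precision matrix not positive definite")
    loglik = (n / 2) * (logdet - np.trace(Sv @ K))
    iu = np.triu_indices(p, k=1)
    E = int((np.abs(K[iu]) > zero_tol).sum())
    return float(-2 * loglik + E * np.log(n) + 4 * E * gamma * np.log(p))


def select_network(
    table: pd.DataFrame,
    gamma: float = 0.5,
    n_points: int = 100,
    min_ratio: float = 0.01,
    communities=None,
    eig_floor: float = 1e-4,
    tol: float = 1e-4,
    max_iter: int = 500,
    zero_tol: float = EDGE_ZERO_TOL,
) -> NetworkModel:
    """EBIC-selected graphical-lasso network from an item table.

    Runs Spearman correlation, PSD repair, the penalty path, one graphical
    lasso per penalty and EBIC scoring, and returns the minimizing model.
    EBIC ties break toward the larger penalty (sparser network).  Weights
    with ``|w| <= zero_tol`` are set exactly to zero.
    """
    if len(table) < 50:
        warnings.warn(f"only {len(table)} rows; network estimates will be "
                      "unstable below ~50")
    corr = repair_psd(spearman_matrix(table), eig_floor=eig_floor)
    path = lambda_path(corr, n_points=n_points, min_ratio=min_ratio)
    names = corr.node_names
    if communities is None:
        communities = infer_communities(names)

    best = None
    records: list[tuple[float, float, int]] = []
    failures = []
    for lam in path:
        try:
            K = graphical_lasso_fit(corr, lam, tol=tol, max_iter=max_iter)
        except EstimationError as exc:
            failures.append((lam, str(exc)))
            continue
        crit = ebic(K, corr, corr.n, gamma=gamma, zero_tol=zero_tol)
        W = precision_to_weights(K)
        W[np.abs(W) <= zero_tol] = 0.0
        iu = np.triu_indices(W.shape[0], k=1)
        records.append((float(lam), crit, int((np.abs(W[iu]) > 0).sum())))
        if best is None or crit < best[1]:  # strict: first (larger lam) wins ties
            best = (float(lam), crit, W)
    if best is None:
        raise EstimationError(
            f"graphical lasso failed at every penalty: {failures[:3]} ...")
    lam_sel, crit_sel, W_sel = best
    return NetworkModel(weights=W_sel, node_names=names,
                        communities=tuple(communities),
                        lambda_selected=lam_sel, ebic_value=crit_sel,
                        n=corr.n, gamma=gamma, path=records)
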