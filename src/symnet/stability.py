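"""Bootstrap accuracy and stability of the estimated network.

Three procedures, all re-running the full estimation pipeline (including
penalty selection) per replicate so the intervals reflect model-selection
variability:

* non-parametric bootstrap of edge weights (rows resampled with
  replacement; percentile 95% CIs);
* bootstrapped difference tests — two edges or two centralities differ if
  the percentile interval of their per-replicate differences excludes 0;
* case-dropping bootstrap — re-estimation on subsamples with an increasing
  fraction of participants removed, summarized by the correlation-stability
  (CS) coefficient: the largest drop fraction at which the subset-vs-full
  statistic correlation stays >= 0.7 with probability >= 0.95.  CS below
  0.25 is inadequate; above 0.5 is ideal.

Per-replicate seeds are derived from the master seed by a counter scheme,
so each replicate's randomness is independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import centrality as _centrality
from .estimation import EstimationError, NetworkModel, select_network

#: drop fractions tested by default, capping the CS-coefficient at 0.75
DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))

STATISTICS = ("EI", "BEI", "edge")


class BootstrapError(RuntimeError):
    pass


def _replicate_rng(seed: int, kind: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, kind, rep)))


def _stat_vector(model: NetworkModel, statistic: str) -> np.ndarray:
    if statistic == "EI":
        return _centrality.expected_influence(model.weights)
    if statistic == "BEI":
        return _centrality.bridge_expected_influence(model.weights,
                                                     model.communities)
    if statistic == "edge":
        iu = np.triu_indices(model.p, k=1)
        return model.weights[iu]
    raise ValueError(f"unknown statistic {statistic!r}; expected one of "
                     f"{STATISTICS}")


@dataclass
class EdgeBootstrap:
    """Point estimates, bootstrap draws and percentile CIs for all edges."""

    model: NetworkModel
    draws: np.ndarray          # (B_ok, p, p) weight matrices
    level: float
    n_failures: int
    seed: int

    @property
    def B(self) -> int:
        return self.draws.shape[0]

    def edge_draws(self, i: int, j: int) -> np.ndarray:
        return self.draws[:, i, j]

    def summary(self) -> pd.DataFrame:
        """Per-pair estimate and CI (all node pairs, zero edges included)."""
        lo_q = (1 - self.level) / 2
        p = self.model.p
        names = self.model.node_names
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                d = self.draws[:, i, j]
                rows.append((names[i], names[j],
                             float(self.model.weights[i, j]),
                             float(np.quantile(d, lo_q)),
                             float(np.quantile(d, 1 - lo_q)),
                             self.B, self.n_failures))
        return pd.DataFrame(rows, columns=["node_a", "node_b", "estimate",
                                           "lower", "upper", "B", "failures"])


def edge_bootstrap(table: pd.DataFrame, B: int = 1000, level: float = 0.95,
                   seed: int = 0, max_failure_rate: float = 0.1,
                   **estimator_kwargs) -> EdgeBootstrap:
    """Non-parametric bootstrap of the edge-weight matrix.

    Rows are resampled with replacement and the whole estimation (penalty
    path and EBIC selection included) is re-run per replicate.  Replicates
    whose estimation fails are skipped and counted; more than
    ``max_failure_rate`` failures is an error.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    model = select_network(table, **estimator_kwargs)
    n = len(table)
    draws, failures = [], 0
    for b in range(B):
        rng = _replicate_rng(seed, 1, b)
        idx = rng.integers(0, n, size=n)
        try:
            m = select_network(table.iloc[idx], **estimator_kwargs)
        except (EstimationError, ValueError):
            failures += 1
            continue
        draws.append(m.weights)
    if failures > max_failure_rate * B:
        raise BootstrapError(
            f"{failures}/{B} bootstrap replicates failed estimation")
    return EdgeBootstrap(model=model, draws=np.array(draws), level=level,
                         n_failures=failures, seed=seed)


def difference_test(draws_a: np.ndarray, draws_b: np.ndarray,
                    alpha: float = 0.05) -> bool:
    """Bootstrapped difference test on paired draws.

    Significant iff the (alpha/2, 1-alpha/2) percentile interval of the
    per-replicate differences excludes zero.
    """
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("draws must be paired (equal length)")
    diff = a - b
    lo = np.quantile(diff, alpha / 2)
    hi = np.quantile(diff, 1 - alpha / 2)
    return bool(lo > 0 or hi < 0)


def edge_difference_matrix(boot: EdgeBootstrap,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise difference tests between the full-sample nonzero edges.

    Long format: one row per unordered pair of edges with the significance
    flag; symmetric by construction.
    """
    p = boot.model.p
    names = boot.model.node_names
    edges = [(i, j) for i in range(p) for j in range(i + 1, p)
             if boot.model.weights[i, j] != 0]
    rows = []
    for a in range(len(edges)):
        for b in range(a + 1, len(edges)):
            (i1, j1), (i2, j2) = edges[a], edges[b]
            sig = difference_test(boot.edge_draws(i1, j1),
                                  boot.edge_draws(i2, j2), alpha=alpha)
            rows.append((f"{names[i1]}--{names[j1]}",
                         f"{names[i2]}--{names[j2]}", sig))
    return pd.DataFrame(rows, columns=["edge_a", "edge_b", "significant"])


def centrality_difference_matrix(boot: EdgeBootstrap, statistic: str = "EI",
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise difference tests between node centralities (EI or BEI)."""
    stat_draws = np.array([_stat_vector(
        NetworkModel(W, boot.model.node_names, boot.model.communities,
                     0.0, 0.0, boot.model.n, boot.model.gamma), statistic)
        for W in boot.draws])
    names = boot.model.node_names
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sig = difference_test(stat_draws[:, a], stat_draws[:, b],
                                  alpha=alpha)
            rows.append((names[a], names[b], sig))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "significant"])


@dataclass
class CaseDropResult:
    """Subset-vs-full statistic correlations from the case-dropping bootstrap."""

    proportions: tuple[float, ...]
    #: statistic -> (len(proportions), B) array of Pearson correlations
    correlations: dict[str, np.ndarray]
    n: int
    B: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for stat, C in self.correlations.items():
            for qi, q in enumerate(self.proportions):
                for b in range(C.shape[1]):
                    rows.append((stat, q, b, C[qi, b]))
        return pd.DataFrame(rows, columns=["statistic", "drop_proportion",
                                           "replicate", "correlation"])


def case_dropping(table: pd.DataFrame, statistic="EI",
                  proportions=DEFAULT_DROP_GRID, B: int = 1000,
                  seed: int = 0, min_rows: int = 20,
                  **estimator_kwargs) -> CaseDropResult:
    """Case-dropping bootstrap for centrality (or edge) stability.

    For each drop proportion q, draws B subsamples of ``ceil((1-q)*n)``
    rows without replacement, re-estimates the network, and records the
    Pearson correlation between the subsample and full-sample statistic
    vectors.  ``statistic`` may be a single name or a sequence (one
    re-estimation per subsample is shared across statistics).
    """
    stats = (statistic,) if isinstance(statistic, str) else tuple(statistic)
    for s in stats:
        if s not in STATISTICS:
            raise ValueError(f"unknown statistic {s!r}")
    props = tuple(float(q) for q in proportions)
    if any(not 0 < q < 1 for q in props) or list(props) != sorted(set(props)):
        raise ValueError("proportions must be strictly increasing in (0, 1)")
    n = len(table)
    if int(np.ceil((1 - max(props)) * n)) < min_rows:
        raise ValueError(
            f"largest drop leaves fewer than {min_rows} of {n} rows")

    full = select_network(table, **estimator_kwargs)
    full_vec = {s: _stat_vector(full, s) for s in stats}
    C = {s: np.full((len(props), B), np.nan) for s in stats}
    failures = 0
    for qi, q in enumerate(props):
        m = int(np.ceil((1 - q) * n))
        for b in range(B):
            rng = _replicate_rng(seed, 2, qi * B + b)
            idx = rng.choice(n, size=m, replace=False)
            try:
                sub = select_network(table.iloc[idx], **estimator_kwargs)
            except (EstimationError, ValueError):
                failures += 1
                continue
            for s in stats:
                v = _stat_vector(sub, s)
                C[s][qi, b] = _safe_pearson(v, full_vec[s])
    if failures > 0.1 * len(props) * B:
        raise BootstrapError(
            f"{failures} case-dropping replicates failed estimation")
    return CaseDropResult(proportions=props, correlations=C, n=n, B=B,
                          seed=seed)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    # constant vectors (e.g. an empty subsample network) carry no ordering
    # information; score them as zero stability rather than NaN
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def cs_coefficient(result: CaseDropResult, statistic: str | None = None,
                   cor_threshold: float = 0.7, prob: float = 0.95):
    """Correlation-stability coefficient per statistic.

    The largest tested drop proportion q such that at least ``prob`` of the
    replicate correlations at q are >= ``cor_threshold``; 0.0 if none
    qualifies.  Returns a float when ``statistic`` is given, else a dict.
    """
    if not result.correlations:
        raise ValueError("empty case-dropping result")

    def one(stat: str) -> float:
        C = result.correlations[stat]
        cs = 0.0
        for qi, q in enumerate(result.proportions):
            row = C[qi]
            row = row[~np.isnan(row)]
            if row.size and (row >= cor_threshold).mean() >= prob:
                cs = q
        return cs

    if statistic is not None:
        return one(statistic)
    return {s: one(s) for s in result.correlations}
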