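"""Node influence statistics: expected influence, bridge EI, strength.

Expected influence (EI) is the signed sum of a node's edge weights — unlike
strength (the absolute sum) it distinguishes activating from inhibiting
edges.  Bridge expected influence (BEI) restricts the signed sum to edges
crossing into the other symptom community and quantifies a node's role in
contagion between disorders.  Raw values are the primary outputs;
z-standardized variants are offered for plotting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import NetworkModel


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    if not np.allclose(np.diag(W), 0.0, atol=1e-12):
        raise ValueError("weight matrix must have zero diagonal")
    return W


def expected_influence(W: np.ndarray) -> np.ndarray:
    """One-step EI: signed row sums of the weight matrix."""
    return _check_weights(W).sum(axis=1)


def strength(W: np.ndarray) -> np.ndarray:
    """Node strength: row sums of absolute weights."""
    return np.abs(_check_weights(W)).sum(axis=1)


def bridge_expected_influence(W: np.ndarray, communities) -> np.ndarray:
    """One-step BEI: signed sum of edges to nodes in other communities."""
    W = _check_weights(W)
    labels = list(communities)
    if len(labels) != W.shape[0]:
        raise ValueError("one community label required per node")
    for i, lab in enumerate(labels):
        if lab is None or (isinstance(lab, float) and np.isnan(lab)):
            raise ValueError(f"node {i} has no community label")
    cross = np.not_equal.outer(np.asarray(labels, dtype=object),
                               np.asarray(labels, dtype=object))
    return (W * cross).sum(axis=1)


def standardize(values) -> np.ndarray:
    """z-scores with the n-1 SD divisor; errors on zero spread."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardize needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread; z-scores undefined")
    return (x - x.mean()) / sd


def centrality_table(model: NetworkModel) -> pd.DataFrame:
    """Per-node EI, BEI and strength (raw and z-standardized)."""
    W = model.weights
    ei = expected_influence(W)
    bei = bridge_expected_influence(W, model.communities)
    st = strength(W)

    def z(x):  # degenerate (e.g. empty-network) statistics get NaN z-scores
        try:
            return standardize(x)
        except ValueError:
            return np.full(len(x), np.nan)

    return pd.DataFrame({
        "node": list(model.node_names),
        "community": list(model.communities),
        "EI": ei,
        "BEI": bei,
        "strength": st,
        "z_EI": z(ei),
        "z_BEI": z(bei),
        "z_strength": z(st),
    })
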