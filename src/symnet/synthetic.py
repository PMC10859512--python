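"""Synthetic ordinal survey data with a known partial-correlation network.

The generator follows a latent-Gaussian (Gaussian copula) threshold model:
each participant draws a latent multivariate-normal vector whose correlation
structure is implied by a user-specified sparse partial-correlation network,
and each coordinate is cut at item-specific thresholds into the 0-3 ordinal
categories of the CESD-10 and GAD-7 screening items.  Survey-style missing
codes can then be injected completely at random.

This makes every downstream stage of the analysis testable against ground
truth: the true network is known, the threshold-implied marginals are known,
and a single integer seed makes every table reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

CESD_ITEMS = tuple(f"CESD{i}" for i in range(1, 11))
GAD_ITEMS = tuple(f"GAD{i}" for i in range(1, 8))
NODE_NAMES = CESD_ITEMS + GAD_ITEMS

DEPRESSION = "depression"
ANXIETY = "anxiety"
DEFAULT_COMMUNITIES = (DEPRESSION,) * 10 + (ANXIETY,) * 7

#: Missing-value tokens emulating "not able to answer" / "don't know" /
#: "not applicable" survey codes.
MISSING_CODES = ("NA_UNABLE", "NA_DK", "NA_NAP")

#: Per-item target means on the 0-3 scale used to calibrate the default
#: thresholds: right-skewed, with anxiety items much rarer than depression
#: items (e.g. sleep disturbance and lack of happiness are common in this
#: population, catastrophic worry is rare).
DEFAULT_ITEM_MEANS = {
    "CESD1": 0.79, "CESD2": 1.02, "CESD3": 0.73, "CESD4": 1.06,
    "CESD5": 1.29, "CESD6": 0.65, "CESD7": 1.45, "CESD8": 0.64,
    "CESD9": 0.50, "CESD10": 1.36,
    "GAD1": 0.32, "GAD2": 0.23, "GAD3": 0.28, "GAD4": 0.20,
    "GAD5": 0.16, "GAD6": 0.20, "GAD7": 0.12,
}

#: Default cross-community ("bridge") edges: the nervousness/anxiety item is
#: weakly tied to several depression items, and "everything was an effort"
#: to excessive worry.  Weights are small (0.05-0.10) relative to
#: within-community edges.
DEFAULT_BRIDGE_EDGES = (
    ("CESD10", "GAD1", 0.10),
    ("CESD3", "GAD1", 0.05),
    ("CESD4", "GAD1", 0.05),
    ("CESD5", "GAD1", 0.05),
    ("CESD6", "GAD1", 0.05),
    ("CESD4", "GAD3", 0.06),
)


class NetworkSpecError(ValueError):
    """An impossible true-network specification (e.g. |weight| >= 1)."""


@dataclass
class TrueNetwork:
    """Ground-truth partial-correlation network used for simulation.

    ``weights[i, j]`` is the partial correlation between items i and j given
    all other items; the implied precision (concentration) matrix has unit
    diagonal and off-diagonal ``-weights[i, j]`` and must be positive
    definite for a Gaussian distribution with this network to exist.
    """

    weights: np.ndarray
    node_names: tuple[str, ...] = NODE_NAMES
    communities: tuple[str, ...] = DEFAULT_COMMUNITIES
    #: factor by which requested weights were uniformly shrunk to reach
    #: positive definiteness (1.0 = no shrinkage applied)
    shrink_factor: float = 1.0

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise NetworkSpecError("weights must be a square matrix")
        if len(self.node_names) != W.shape[0]:
            raise NetworkSpecError("node_names length must match weights")
        if len(self.communities) != W.shape[0]:
            raise NetworkSpecError("communities length must match weights")
        if not np.allclose(W, W.T, atol=1e-12):
            raise NetworkSpecError("weights must be symmetric")
        bad = np.argwhere(np.abs(W) >= 1)
        bad = bad[bad[:, 0] != bad[:, 1]]
        if len(bad):
            i, j = bad[0]
            raise NetworkSpecError(
                f"edge ({self.node_names[i]}, {self.node_names[j]}) has "
                f"|weight| >= 1: {W[i, j]}"
            )
        np.fill_diagonal(W, 0.0)
        self.weights = W
        self.node_names = tuple(self.node_names)
        self.communities = tuple(self.communities)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def precision(self) -> np.ndarray:
        """Concentration matrix implied by the partial correlations."""
        K = -self.weights.copy()
        np.fill_diagonal(K, 1.0)
        return K

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                if self.weights[i, j] != 0:
                    out.append((self.node_names[i], self.node_names[j],
                                float(self.weights[i, j])))
        return out


def make_true_network(
    n_dep: int = 10,
    n_anx: int = 7,
    within_weight_range: tuple[float, float] = (0.05, 0.35),
    bridge_edges=DEFAULT_BRIDGE_EDGES,
    density: float = 0.35,
    seed: int = 0,
    eig_floor: float = 0.05,
) -> TrueNetwork:
    """Draw a random two-community true network.

    Within each community a fraction ``density`` of the possible pairs get an
    edge with weight uniform in ``within_weight_range``; cross-community
    edges are fixed by ``bridge_edges`` (item-name pairs with weights).  If
    the implied precision matrix is not positive definite, all weights are
    uniformly shrunk toward zero until its minimum eigenvalue exceeds
    ``eig_floor``; the applied factor is recorded on the result.
    """
    lo, hi = within_weight_range
    if not (-1 < lo <= hi < 1):
        raise NetworkSpecError(
            f"within_weight_range {within_weight_range} must lie in (-1, 1)")
    if not 0 <= density <= 1:
        raise NetworkSpecError(f"density {density} outside [0, 1]")

    names = tuple(f"CESD{i}" for i in range(1, n_dep + 1)) + tuple(
        f"GAD{i}" for i in range(1, n_anx + 1))
    communities = (DEPRESSION,) * n_dep + (ANXIETY,) * n_anx
    p = n_dep + n_anx
    idx = {name: i for i, name in enumerate(names)}

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11CE)))
    W = np.zeros((p, p))
    for start, size in ((0, n_dep), (n_dep, n_anx)):
        pairs = [(i, j) for i in range(start, start + size)
                 for j in range(i + 1, start + size)]
        k = int(round(density * len(pairs)))
        chosen = rng.choice(len(pairs), size=k, replace=False)
        for c in chosen:
            i, j = pairs[c]
            W[i, j] = W[j, i] = rng.uniform(lo, hi)
    for a, b, w in bridge_edges:
        if a not in idx or b not in idx:
            raise NetworkSpecError(f"bridge edge ({a}, {b}) names unknown node")
        if not -1 < w < 1:
            raise NetworkSpecError(
                f"bridge edge ({a}, {b}) has impossible weight {w}")
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w

    W, shrink = _shrink_to_pd(W, eig_floor)
    return TrueNetwork(W, names, communities, shrink_factor=shrink)


def _shrink_to_pd(W: np.ndarray, eig_floor: float) -> tuple[np.ndarray, float]:
    """Uniformly shrink weights until min eigenvalue of precision > floor."""
    shrink = 1.0
    for _ in range(200):
        K = -shrink * W
        np.fill_diagonal(K, 1.0)
        if np.linalg.eigvalsh(K)[0] > eig_floor:
            return shrink * W, shrink
        shrink *= 0.95
    raise NetworkSpecError(
        "could not reach positive definiteness by uniform shrinkage")


def true_covariance(net: TrueNetwork) -> np.ndarray:
    """Latent correlation matrix implied by the true network.

    Inverts the precision matrix and rescales to unit diagonal; converting
    the result back through precision -> partial correlations recovers
    ``net.weights`` exactly (up to floating point).
    """
    K = net.precision()
    eig_min = np.linalg.eigvalsh(K)[0]
    if eig_min <= 0:
        raise NetworkSpecError(
            f"implied precision not positive definite (min eig {eig_min:.3g})")
    C = np.linalg.inv(K)
    d = 1.0 / np.sqrt(np.diag(C))
    return d[:, None] * C * d[None, :]


@dataclass
class ThresholdSet:
    """Per-item cut points on the latent standard-normal scale.

    ``cuts[i]`` holds three strictly increasing values; a latent draw z maps
    to the ordinal response ``sum(z > cuts[i])`` in {0, 1, 2, 3}.
    """

    cuts: np.ndarray
    item_names: tuple[str, ...] = NODE_NAMES

    def __post_init__(self) -> None:
        cuts = np.asarray(self.cuts, dtype=float)
        if cuts.ndim != 2 or cuts.shape[1] != 3:
            raise ValueError("cuts must be an (items, 3) array")
        if not np.all(np.diff(cuts, axis=1) > 0):
            raise ValueError("cut points must be strictly increasing per item")
        if len(self.item_names) != cuts.shape[0]:
            raise ValueError("item_names length must match cuts")
        self.cuts = cuts
        self.item_names = tuple(self.item_names)

    @property
    def n_items(self) -> int:
        return self.cuts.shape[0]

    def category_probs(self) -> np.ndarray:
        """(items, 4) matrix of category probabilities; rows sum to 1."""
        cdf = norm.cdf(self.cuts)
        padded = np.hstack([np.zeros((self.n_items, 1)), cdf,
                            np.ones((self.n_items, 1))])
        return np.diff(padded, axis=1)

    def implied_means(self) -> np.ndarray:
        """Expected ordinal response per item: sum_k P(Z > cut_k)."""
        return norm.sf(self.cuts).sum(axis=1)

    @classmethod
    def from_means(cls, means, item_names=NODE_NAMES,
                   gaps: tuple[float, float] = (0.9, 0.9)) -> "ThresholdSet":
        """Calibrate thresholds so each item's implied mean matches a target.

        Cut points are parameterized as (c, c+gaps[0], c+gaps[0]+gaps[1])
        and the offset c is solved per item by root finding; fixed gaps give
        the right-skewed category profile typical of these screeners.
        """
        means = np.asarray(means, dtype=float)
        if np.any(means <= 0) or np.any(means >= 3):
            raise ValueError("target means must lie strictly in (0, 3)")
        offsets = np.array([0.0, gaps[0], gaps[0] + gaps[1]])

        def implied(c: float, target: float) -> float:
            return norm.sf(c + offsets).sum() - target

        cuts = np.empty((len(means), 3))
        for i, m in enumerate(means):
            c = brentq(implied, -10, 10, args=(m,))
            cuts[i] = c + offsets
        return cls(cuts, item_names)


def default_thresholds() -> ThresholdSet:
    """Thresholds calibrated to the default right-skewed item means."""
    means = [DEFAULT_ITEM_MEANS[name] for name in NODE_NAMES]
    return ThresholdSet.from_means(means, NODE_NAMES)


def sample_ordinal(
    cov: np.ndarray,
    thresholds: ThresholdSet,
    n: int,
    seed: int = 0,
    mean_age: float = 80.5,
    sd_age: float = 10.0,
    age_range: tuple[int, int] = (65, 109),
) -> pd.DataFrame:
    """Draw a raw survey table of n participants.

    Latent vectors are multivariate normal with correlation ``cov`` and are
    discretized by ``thresholds``.  Ages are truncated-normal integers and
    the diabetes flag is set for everyone (the generator emulates an extract
    of diagnosed participants); both exist so the eligibility filter has
    real columns to act on.
    """
    cov = np.asarray(cov, dtype=float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if cov.shape[0] != thresholds.n_items:
        raise ValueError(
            f"cov dimension {cov.shape[0]} does not match "
            f"{thresholds.n_items} thresholded items")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5A3D)))
    L = np.linalg.cholesky(cov)
    Z = rng.standard_normal((n, cov.shape[0])) @ L.T
    X = (Z[:, :, None] > thresholds.cuts[None, :, :]).sum(axis=2)

    lo, hi = age_range
    a, b = (lo - mean_age) / sd_age, (hi - mean_age) / sd_age
    from scipy.stats import truncnorm
    ages = truncnorm.rvs(a, b, loc=mean_age, scale=sd_age, size=n,
                         random_state=rng).round().astype(int)

    table = pd.DataFrame({"participant_id": np.arange(1, n + 1),
                          "age": ages,
                          "dm_diagnosed": np.ones(n, dtype=int)})
    for k, name in enumerate(thresholds.item_names):
        table[name] = X[:, k]
    return table


def inject_missing(table: pd.DataFrame, rate: float, seed: int = 0,
                   codes=MISSING_CODES,
                   item_names=None) -> pd.DataFrame:
    """Replace a fraction of item cells, uniformly at random, with missing codes.

    Missingness is completely at random, which is all a complete-case
    analysis can be sensitive to.  ``rate`` 0 returns a copy unchanged.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"rate {rate} outside [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    if item_names is None:
        item_names = [c for c in table.columns if c in NODE_NAMES]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x3155)))
    mask = rng.random((len(out), len(item_names))) < rate
    which = rng.integers(0, len(codes), size=mask.shape)
    for k, col in enumerate(item_names):
        if mask[:, k].any():
            vals = out[col].astype(object)
            vals[mask[:, k]] = [codes[w] for w in which[mask[:, k], k]]
            out[col] = vals
    return out


#: Strong within-community edges anchoring the default study network:
#: hopelessness pairs with lack of happiness, feeling bothered with
#: depressed mood, loneliness with inability to get going, concentration
#: trouble with effort; uncontrollable/excessive worry and
#: restlessness/irritability pair within the anxiety community.
STUDY_ANCHOR_EDGES = (
    ("CESD5", "CESD7", 0.39),
    ("CESD1", "CESD3", 0.33),
    ("CESD8", "CESD9", 0.30),
    ("GAD5", "GAD6", 0.30),
    ("GAD2", "GAD3", 0.29),
    ("CESD2", "CESD4", 0.26),
)


def study_network(seed: int = 0,
                  filler_weight_range: tuple[float, float] = (0.05, 0.18),
                  filler_density: float = 0.35,
                  eig_floor: float = 0.05) -> TrueNetwork:
    """The default 17-node, two-community network used by simulate_study.

    Deterministic anchor edges carry the characteristic structure (a few
    strong within-community partial correlations of 0.26-0.39 in both
    communities, weak 0.05-0.10 bridges concentrated on the
    nervousness/anxiety item); seeded random filler edges among the
    remaining within-community pairs give every node some connectivity.
    """
    p = len(NODE_NAMES)
    idx = {name: i for i, name in enumerate(NODE_NAMES)}
    W = np.zeros((p, p))
    anchored = set()
    for a, b, w in STUDY_ANCHOR_EDGES + DEFAULT_BRIDGE_EDGES:
        i, j = idx[a], idx[b]
        W[i, j] = W[j, i] = w
        anchored.add((min(i, j), max(i, j)))

    lo, hi = filler_weight_range
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x57DD)))
    for start, size in ((0, 10), (10, 7)):
        pairs = [(i, j) for i in range(start, start + size)
                 for j in range(i + 1, start + size)
                 if (i, j) not in anchored]
        k = int(round(filler_density * len(pairs)))
        for c in rng.choice(len(pairs), size=k, replace=False):
            i, j = pairs[c]
            W[i, j] = W[j, i] = rng.uniform(lo, hi)

    W, shrink = _shrink_to_pd(W, eig_floor)
    return TrueNetwork(W, NODE_NAMES, DEFAULT_COMMUNITIES,
                       shrink_factor=shrink)


def partial_correlations(corr: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix from a (nonsingular) correlation matrix."""
    K = np.linalg.inv(corr)
    d = 1.0 / np.sqrt(np.diag(K))
    W = -(d[:, None] * K * d[None, :])
    np.fill_diagonal(W, 0.0)
    return W
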