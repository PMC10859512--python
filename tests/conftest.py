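import numpy as np
import pytest

from symnet.synthetic import ThresholdSet, TrueNetwork

SMALL_NAMES = ("CESD1", "CESD2", "CESD3", "GAD1", "GAD2", "GAD3")
SMALL_COMMUNITIES = ("depression",) * 3 + ("anxiety",) * 3


def small_true_network() -> TrueNetwork:
    """6-node two-community network used for reduced-scale experiments."""
    W = np.zeros((6, 6))
    for i, j, w in [(0, 1, 0.30), (1, 2, 0.25), (0, 2, 0.20),
                    (3, 4, 0.30), (4, 5, 0.25), (2, 3, 0.10)]:
        W[i, j] = W[j, i] = w
    return TrueNetwork(W, SMALL_NAMES, SMALL_COMMUNITIES)


def small_thresholds() -> ThresholdSet:
    return ThresholdSet.from_means([0.8, 1.0, 0.7, 0.35, 0.25, 0.3],
                                   SMALL_NAMES)


@pytest.fixture(scope="session")
def small_net() -> TrueNetwork:
    return small_true_network()


@pytest.fixture(scope="session")
def small_thr() -> ThresholdSet:
    return small_thresholds()


@pytest.fixture(scope="session")
def study_table():
    """One complete-case synthetic survey shared across tests."""
    import symnet as sn
    net = sn.study_network(seed=1)
    cov = sn.true_covariance(net)
    return sn.sample_ordinal(cov, sn.default_thresholds(), n=1000, seed=42)
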