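"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own recursions: HMM
quantities are computed by exhaustive enumeration over all state paths, and
tail probabilities by direct series summation, so agreement is a genuine
cross-check.
"""

import itertools
import math

import numpy as np
import pytest

from chromstate.genome_io import BinnedGenome, BinaryTrackSet
from chromstate.hmm import ChromatinModel


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def enumerate_paths(model: ChromatinModel, X: np.ndarray):
    """Exact likelihood and per-bin posteriors by summing over all K^T paths."""
    T = len(X)
    K = model.K
    total = 0.0
    post = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        p = model.pi[path[0]]
        for t in range(1, T):
            p *= model.A[path[t - 1], path[t]]
        for t in range(T):
            for m in range(model.M):
                e = model.E[path[t], m]
                p *= e if X[t, m] else (1.0 - e)
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return total, post / total


def poisson_tail_bruteforce(lam: float, observed: int, terms: int = 200) -> float:
    """P(X >= observed) by direct series summation of the Poisson pmf."""
    if observed <= 0:
        return 1.0
    below = sum(math.exp(-lam) * lam**k / math.factorial(k) for k in range(observed))
    return 1.0 - below


def match_states(E_fit: np.ndarray, E_true: np.ndarray) -> np.ndarray:
    """Hungarian matching of fitted to true states on emission rows.

    Returns ``perm`` with fitted state ``perm[j]`` matched to true state ``j``.
    """
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(E_fit[:, None, :] - E_true[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(cols), dtype=int)
    perm[cols] = rows
    return perm


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def tiny_genome():
    return BinnedGenome((("chr1", 1200),), bin_size=200)  # 6 bins


@pytest.fixture
def small_model():
    """K=3, M=2 model with distinct emission rows for enumeration checks."""
    return ChromatinModel(
        marks=["m1", "m2"],
        pi=[0.5, 0.3, 0.2],
        A=[[0.8, 0.1, 0.1], [0.2, 0.7, 0.1], [0.1, 0.2, 0.7]],
        E=[[0.9, 0.1], [0.5, 0.5], [0.1, 0.8]],
    )


@pytest.fixture
def two_state_truth():
    """The standard recovery instance: K=2, M=3, blockwise emissions, self-transition 0.9."""
    return ChromatinModel(
        marks=["m1", "m2", "m3"],
        pi=[0.5, 0.5],
        A=[[0.9, 0.1], [0.1, 0.9]],
        E=[[0.9, 0.9, 0.1], [0.1, 0.1, 0.9]],
    )


def tracks_from_matrix(genome: BinnedGenome, X: np.ndarray, marks=None, condition="test"):
    marks = marks or [f"m{i+1}" for i in range(X.shape[1])]
    return BinaryTrackSet(genome, condition, marks, {"chr1": np.asarray(X, dtype=np.uint8)})
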