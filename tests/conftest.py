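"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (exhaustive enumeration, quadratic
loops, closed forms) and independent of the package's implementation paths.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest

from lymphosig import ExpressionMatrix, Partition


def brute_force_mca(p: Partition, q: Partition) -> float:
    """MCA by exhaustive search over all injective cluster-label mappings."""
    assert p.sample_ids == q.sample_ids
    s = p.n_samples
    kp, kq = p.k, q.k
    best = 0
    if kp <= kq:
        small, large = p.assignment, q.assignment
        k_small, k_large = kp, kq
    else:
        small, large = q.assignment, p.assignment
        k_small, k_large = kq, kp
    for image in itertools.permutations(range(1, k_large + 1), k_small):
        mapping = dict(zip(range(1, k_small + 1), image))
        agree = sum(1 for a, b in zip(small, large) if mapping[a] == b)
        best = max(best, agree)
    return best / s


def hypergeom_upper_tail(k: int, n_universe: int, n_category: int, n_signature: int) -> float:
    """P(overlap >= k) as an explicit sum of hypergeometric point masses."""
    total = comb(n_universe, n_signature)
    upper = min(n_category, n_signature)
    return sum(
        comb(n_category, i) * comb(n_universe - n_category, n_signature - i)
        for i in range(k, upper + 1)
    ) / total


def bh_stepup_direct(p: np.ndarray) -> np.ndarray:
    """Quadratic-time transcription of the BH step-up definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[rank_j - 1]] * m / rank_j for rank_j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def random_partition_pair(rng: np.random.Generator, max_s: int = 12, max_k: int = 4):
    """A pair of random valid partitions over a shared sample set."""
    s = int(rng.integers(2, max_s + 1))
    ids = [f"s{i}" for i in range(s)]
    parts = []
    for _ in range(2):
        k = int(rng.integers(1, min(max_k, s) + 1))
        while True:
            assignment = rng.integers(1, k + 1, size=s)
            if len(np.unique(assignment)) == k:
                break
        parts.append(Partition(assignment, k, ids))
    return parts[0], parts[1]


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [5.5, 6.5, 7.5, 8.5],
            [9.0, 8.0, 7.0, 6.0],
        ]
    )
    return ExpressionMatrix(values, ["ga", "gb", "gc"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def two_blob_matrix() -> ExpressionMatrix:
    """Two well-separated sample groups (10 + 10) on 30 genes."""
    rng = np.random.default_rng(42)
    values = rng.normal(8.0, 0.5, size=(30, 20))
    values[:10, 10:] += 4.0
    ids = [f"g{i}" for i in range(30)]
    samples = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
    return ExpressionMatrix(values, ids, samples)
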