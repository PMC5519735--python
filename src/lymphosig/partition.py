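"""Sample partitions and the maximum-cluster-agreement (MCA) index.

A :class:`Partition` assigns every sample to one of ``k`` non-empty clusters.
The MCA index between two partitions of the same samples is the fraction of
samples that fall in matched clusters under the best injective matching of
cluster labels — computed exactly as a maximum-weight bipartite matching on
the contingency table.  It is 1 exactly when the partitions coincide up to a
relabeling of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .io import ExpressionMatrix

__all__ = [
    "Partition",
    "mca_index",
    "random_partition",
    "hierarchical_partition",
    "kmeans_partition",
    "partition_agreement_on_common",
]


@dataclass
class Partition:
    """Assignment of samples to clusters ``1..k``."""

    assignment: np.ndarray
    k: int
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.assignment.ndim != 1 or len(self.assignment) != len(self.sample_ids):
            raise ValueError("assignment length must equal the number of samples")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        present = set(self.assignment.tolist())
        if not present.issubset(range(1, self.k + 1)):
            raise ValueError(f"cluster labels {sorted(present)} outside 1..{self.k}")
        if len(present) != self.k:
            missing = sorted(set(range(1, self.k + 1)) - present)
            raise ValueError(f"empty cluster(s): {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for sid, c in zip(self.sample_ids, self.assignment):
            out[int(c)].append(sid)
        return out

    def restrict(self, sample_ids: list[str]) -> "Partition":
        """Restrict to a sample subset, dropping emptied clusters (labels compacted)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample(s): {', '.join(missing)}")
        sub = self.assignment[[index[s] for s in sample_ids]]
        return Partition(_canonical_relabel(sub), len(np.unique(sub)), list(sample_ids))


def _canonical_relabel(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first occurrence (reproducible output)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, c in enumerate(raw):
        c = int(c)
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    return out


def mca_index(p: Partition, q: Partition) -> float:
    """Partition agreement in [0, 1] via optimal cluster-label matching.

    Aligns the two partitions by sample id, builds the ``k_p x k_q``
    contingency table, pads it square with zeros, and solves the assignment
    problem; the index is the matched count divided by the number of samples.
    Symmetric, invariant under cluster relabeling.
    """
    sp, sq = set(p.sample_ids), set(q.sample_ids)
    if sp != sq:
        diff = sorted(sp.symmetric_difference(sq))
        raise ValueError(f"partitions cover different samples; symmetric difference: {diff}")
    if p.sample_ids == q.sample_ids:
        q_aligned = q.assignment
    else:
        pos = {s: i for i, s in enumerate(q.sample_ids)}
        q_aligned = q.assignment[[pos[s] for s in p.sample_ids]]
    table = np.zeros((p.k, q.k), dtype=int)
    np.add.at(table, (p.assignment - 1, q_aligned - 1), 1)
    size = max(p.k, q.k)
    padded = np.zeros((size, size), dtype=int)
    padded[: p.k, : q.k] = table
    rows, cols = linear_sum_assignment(padded, maximize=True)
    return float(padded[rows, cols].sum()) / p.n_samples


def random_partition(sample_ids: list[str], k: int, seed: int) -> Partition:
    """Uniform random assignment into ``k`` clusters, conditioned on none empty.

    Resamples i.i.d.-uniform assignments until all clusters are occupied,
    which draws uniformly from the surjective assignments.
    """
    n = len(sample_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} samples")
    rng = np.random.default_rng(int(seed))
    while True:
        assignment = rng.integers(1, k + 1, size=n)
        if len(np.unique(assignment)) == k:
            return Partition(assignment, k, list(sample_ids))


def _sample_distances(x: ExpressionMatrix, distance: str) -> np.ndarray:
    profiles = x.values.T  # samples are the clustered units
    if distance == "euclidean":
        return pdist(profiles, metric="euclidean")
    if distance == "one_minus_pearson":
        sd = profiles.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValueError(
                "zero-variance sample(s) under correlation distance: "
                + ", ".join(x.sample_ids[i] for i in flat)
            )
        corr = np.corrcoef(profiles)
        d = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
        return squareform(d, checks=False)
    raise ValueError(f"unknown distance {distance!r}")


def hierarchical_partition(
    x: ExpressionMatrix,
    k: int,
    distance: str = "euclidean",
    linkage_method: str = "average",
) -> Partition:
    """Cut an agglomerative dendrogram of the samples into ``k`` groups."""
    s = x.n_samples
    if not 1 <= k <= s:
        raise ValueError(f"k={k} outside 1..{s}")
    if linkage_method not in ("average", "complete", "ward"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    if k == s:
        return Partition(np.arange(1, s + 1), s, list(x.sample_ids))
    d = _sample_distances(x, distance)
    tree = linkage(d, method=linkage_method)
    raw = fcluster(tree, t=k, criterion="maxclust")
    labels = _canonical_relabel(raw)
    return Partition(labels, int(labels.max()), list(x.sample_ids))


def kmeans_partition(x: ExpressionMatrix, k: int, restarts: int = 10, seed: int = 0) -> Partition:
    """Best-inertia k-means over seeded restarts; clusters canonically relabeled."""
    s = x.n_samples
    if not 1 <= k <= s:
        raise ValueError(f"k={k} outside 1..{s}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed) % (2**32))
    raw = km.fit_predict(x.values.T)
    labels = _canonical_relabel(raw + 1)
    return Partition(labels, int(labels.max()), list(x.sample_ids))


def partition_agreement_on_common(p: Partition, q: Partition) -> float:
    """MCA index on the shared samples of two partitions (>= 2 required)."""
    shared = [s for s in p.sample_ids if s in set(q.sample_ids)]
    if len(shared) < 2:
        raise ValueError(f"partitions share only {len(shared)} sample(s); need >= 2")
    return mca_index(p.restrict(shared), q.restrict(shared))
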