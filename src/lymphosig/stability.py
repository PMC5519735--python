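"""Resampling-based estimation of the number of clusters.

For each candidate ``k`` the procedure repeatedly draws two independent
subsamples of the cohort, clusters each with seeded k-means, and scores the
agreement of the two partitions on their shared samples with the MCA index.
A stable structure yields high agreement.

The "random clustering" baseline comes from running the *identical*
protocol on structure-destroyed data: reference matrices in which every
gene's values have been independently permuted across samples, preserving
each gene's marginal distribution while removing all between-gene and
between-sample structure.  Clustering the permuted cohort with the same
paired-subsample k-means is essential: the two subsamples share samples, so
k-means agreement exceeds that of independent random partitions even on
pure noise, and only a baseline that preserves this coupling is calibrated.

Significance is assessed with an exact matrix-level permutation test.  Under
the no-structure null hypothesis the data matrix is exchangeable with its
gene-wise permutations, so the per-k mean MCA of the data, standardized
against the reference distribution and compared through the maximum z-score
across the candidate range, yields family-wise-calibrated p-values: with R
reference matrices the probability that any k appears significant on a
structureless cohort is at most 1/(R + 1).  Replicate-level two-sample
tests (e.g. a rank-sum of the B data MCA values against baseline values)
are anti-conservative here because all B replicates share one matrix and
are therefore correlated; the matrix-level test is immune to that.

The selected number of clusters is, among the significant k, the one whose
partitioning is most stable (maximal median MCA, ties resolved toward the
larger k) — the most stable demonstrably non-random cluster solution.  The
largest-significant-k accessor is available via :func:`select_k` with
``rule="highest_significant"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .partition import kmeans_partition, partition_agreement_on_common

__all__ = ["StabilityProfile", "stability_profile", "select_k", "ClusterStability", "ClusterStabilityResults"]


@dataclass
class StabilityProfile:
    """Per-k MCA distributions (data vs. permuted baseline) and significance.

    ``p_per_k`` holds family-wise adjusted permutation p-values when
    ``p_adjusted`` is True (the output of :func:`stability_profile`); the
    significance threshold is then ``alpha`` directly.  With
    ``p_adjusted=False`` the p-values are treated as raw per-k values and
    Bonferroni-corrected over the candidate range.
    """

    k_range: list[int]
    mca_data: dict[int, np.ndarray]
    mca_random: dict[int, np.ndarray]
    p_per_k: dict[int, float]
    k_selected: int | None
    alpha: float
    n_resamples: int
    subsample_fraction: float
    seed: int
    p_adjusted: bool = True
    n_references: int = 0
    ref_replicates: int = 0

    def __post_init__(self) -> None:
        for store in (self.mca_data, self.mca_random):
            for k, vals in store.items():
                vals = np.asarray(vals, dtype=float)
                if np.any((vals < 0) | (vals > 1)):
                    raise ValueError(f"MCA values outside [0, 1] at k={k}")
                store[k] = vals
        if any(not 0 <= p <= 1 for p in self.p_per_k.values()):
            raise ValueError("p-values outside [0, 1]")
        if self.k_selected is not None and self.k_selected not in self.k_range:
            raise ValueError("k_selected outside the candidate range")

    def significance_threshold(self) -> float:
        return self.alpha if self.p_adjusted else self.alpha / len(self.k_range)


def select_k(profile: StabilityProfile, rule: str = "max_stability") -> int | None:
    """Select the number of clusters from a stability profile.

    ``rule="max_stability"`` (default): among the k whose data-vs-baseline
    difference is significant, return the one with maximal median data MCA,
    ties resolved toward the larger k — the most stable demonstrably
    non-random partitioning.  ``rule="highest_significant"``: the largest
    significant k.  None if no k is significant.  Pure accessor,
    re-derivable from the profile.
    """
    threshold = profile.significance_threshold()
    significant = [k for k in profile.k_range if profile.p_per_k[k] < threshold]
    if not significant:
        return None
    if rule == "highest_significant":
        return max(significant)
    if rule == "max_stability":
        return max(significant, key=lambda k: (float(np.median(profile.mca_data[k])), k))
    raise ValueError(f"unknown selection rule {rule!r}")


def _permute_genewise(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each gene's values across samples."""
    out = np.empty_like(values)
    for g in range(values.shape[0]):
        out[g] = values[g, rng.permutation(values.shape[1])]
    return out


def _paired_subsample_mca(
    x: ExpressionMatrix,
    k: int,
    rng: np.random.Generator,
    m: int,
    restarts: int,
    max_redraws: int,
) -> float:
    ids = np.asarray(x.sample_ids, dtype=object)
    for _ in range(max_redraws):
        sub_a = sorted(rng.choice(len(ids), size=m, replace=False).tolist())
        sub_b = sorted(rng.choice(len(ids), size=m, replace=False).tolist())
        shared = sorted(set(sub_a) & set(sub_b))
        if len(shared) < max(k, 2):
            continue
        ids_a, ids_b = ids[sub_a].tolist(), ids[sub_b].tolist()
        pa = kmeans_partition(x.subset_samples(ids_a), k, restarts, int(rng.integers(2**31)))
        pb = kmeans_partition(x.subset_samples(ids_b), k, restarts, int(rng.integers(2**31)))
        return partition_agreement_on_common(pa, pb)
    raise RuntimeError(
        f"subsample intersection persistently below k={k}; increase subsample_fraction"
    )


def stability_profile(
    x: ExpressionMatrix,
    k_range,
    B: int = 50,
    subsample_fraction: float = 0.8,
    restarts: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    n_references: int = 24,
    ref_replicates: int = 5,
) -> StabilityProfile:
    """Paired-subsample MCA stability curve over a range of cluster numbers.

    Parameters
    ----------
    k_range : (lo, hi) pair or iterable of int
        Candidate cluster numbers (a 2-tuple is read as an inclusive range).
    B : int
        Resampling replicates per k for the data arm (at least 10).
    subsample_fraction : float
        Fraction f of samples per subsample, 0.5 <= f < 1; each subsample
        has ``ceil(f * S)`` samples and replicates whose intersection is
        smaller than k are redrawn.
    n_references, ref_replicates : int
        R gene-wise permuted reference matrices, each scored with B'
        subsample pairs per k; the family-wise error of declaring any k
        significant on a structureless cohort is at most 1/(R + 1).
    """
    ks = list(range(k_range[0], k_range[1] + 1)) if len(tuple(k_range)) == 2 else sorted(k_range)
    ks = sorted(set(int(k) for k in ks))
    if B < 10:
        raise ValueError("need at least B=10 resampling replicates")
    if 1.0 / (n_references + 1) >= alpha:
        raise ValueError(
            f"{n_references} reference matrices cannot resolve alpha={alpha}: "
            f"the smallest attainable p is 1/{n_references + 1}; use n_references "
            f"> {int(np.ceil(1 / alpha)) - 1}"
        )
    if not 0.5 <= subsample_fraction < 1:
        raise ValueError("subsample_fraction must lie in [0.5, 1)")
    s = x.n_samples
    m = int(np.ceil(subsample_fraction * s))
    if max(ks) >= m:
        raise ValueError(
            f"max k ({max(ks)}) must be below the subsample size ({m}); "
            "raise subsample_fraction or drop large k"
        )

    # data arm: B paired-subsample MCA values per k
    mca_data: dict[int, np.ndarray] = {}
    for k in ks:
        rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(0, k)))
        mca_data[k] = np.array(
            [_paired_subsample_mca(x, k, rng, m, restarts, 100 * B) for _ in range(B)]
        )

    # reference arm: R permuted matrices, B' pairs per k each
    t_ref = np.empty((n_references, len(ks)))
    ref_values: dict[int, list[float]] = {k: [] for k in ks}
    for r in range(n_references):
        rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(1, r)))
        xp = ExpressionMatrix(_permute_genewise(x.values, rng), x.gene_ids, x.sample_ids)
        for j, k in enumerate(ks):
            vals = [
                _paired_subsample_mca(xp, k, rng, m, restarts, 100 * B)
                for _ in range(ref_replicates)
            ]
            ref_values[k].extend(vals)
            t_ref[r, j] = float(np.mean(vals))

    # max-z permutation p-values: exchangeability of the data matrix with its
    # gene-wise permutations under the no-structure null gives exact FWER
    t_data = np.array([float(np.mean(mca_data[k])) for k in ks])
    mu = t_ref.mean(axis=0)
    sd = np.maximum(t_ref.std(axis=0, ddof=1), 1e-12)
    z_data = (t_data - mu) / sd
    z_ref_max = ((t_ref - mu) / sd).max(axis=1)
    p_per_k = {
        k: float((1 + np.sum(z_ref_max >= z_data[j])) / (1 + n_references))
        for j, k in enumerate(ks)
    }

    profile = StabilityProfile(
        ks,
        mca_data,
        {k: np.array(v) for k, v in ref_values.items()},
        p_per_k,
        None,
        alpha,
        B,
        subsample_fraction,
        int(seed),
        p_adjusted=True,
        n_references=n_references,
        ref_replicates=ref_replicates,
    )
    profile.k_selected = select_k(profile)
    return profile


class ClusterStability:
    """Model front-end for cluster-number estimation on a cohort.

    Examples
    --------
    >>> res = ClusterStability(matrix).fit(k_range=(2, 6), seed=7)   # doctest: +SKIP
    >>> res.k_selected
    3
    """

    def __init__(self, x: ExpressionMatrix):
        self.x = x

    def fit(
        self,
        k_range=(2, 6),
        n_resamples: int = 50,
        subsample_fraction: float = 0.8,
        restarts: int = 10,
        alpha: float = 0.05,
        seed: int = 0,
        n_references: int = 24,
        ref_replicates: int = 5,
    ) -> "ClusterStabilityResults":
        profile = stability_profile(
            self.x,
            k_range,
            n_resamples,
            subsample_fraction,
            restarts,
            alpha,
            seed,
            n_references,
            ref_replicates,
        )
        return ClusterStabilityResults(self, profile)


@dataclass
class ClusterStabilityResults:
    model: ClusterStability
    profile: StabilityProfile
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def k_selected(self) -> int | None:
        return self.profile.k_selected

    @property
    def p_per_k(self) -> dict[int, float]:
        return dict(self.profile.p_per_k)

    def summary(self) -> pd.DataFrame:
        """Per-k MCA medians, adjusted permutation p and significance flag."""
        if self._frame is None:
            pr = self.profile
            thr = pr.significance_threshold()
            self._frame = pd.DataFrame(
                {
                    "k": pr.k_range,
                    "mca_data_median": [float(np.median(pr.mca_data[k])) for k in pr.k_range],
                    "mca_random_median": [float(np.median(pr.mca_random[k])) for k in pr.k_range],
                    "p_value": [pr.p_per_k[k] for k in pr.k_range],
                    "significant": [pr.p_per_k[k] < thr for k in pr.k_range],
                }
            )
        return self._frame

    def plot_profile(self, ax=None):
        """Side-by-side box plots of data vs. baseline MCA distributions per k."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(self.profile.k_range) + 2, 4))
        pr = self.profile
        positions_d = [2 * i for i in range(len(pr.k_range))]
        positions_r = [2 * i + 0.7 for i in range(len(pr.k_range))]
        bd = ax.boxplot([pr.mca_data[k] for k in pr.k_range], positions=positions_d, widths=0.6, patch_artist=True)
        br = ax.boxplot([pr.mca_random[k] for k in pr.k_range], positions=positions_r, widths=0.6, patch_artist=True)
        for box in bd["boxes"]:
            box.set_facecolor("tab:red")
        for box in br["boxes"]:
            box.set_facecolor("tab:blue")
        ax.set_xticks([p + 0.35 for p in positions_d])
        ax.set_xticklabels([str(k) for k in pr.k_range])
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("MCA index")
        if pr.k_selected is not None:
            ax.set_title(f"selected k = {pr.k_selected}")
        return ax
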