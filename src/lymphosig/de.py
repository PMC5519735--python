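"""Shrinkage-t differential expression and category over-representation.

The moderated two-sample statistic stabilizes per-gene variance estimates by
shrinking them toward the across-gene median pooled variance with an
analytically estimated intensity.  For gene ``g`` with group means
``mean_A``, ``mean_B`` and within-group centered residuals ``r_gi`` over all
``n = n_A + n_B`` samples:

    delta_g   = mean_A - mean_B                       (signed log2 fold change)
    v_g       = sum_i r_gi^2 / (n - 2)                (pooled variance)
    v_median  = median_g v_g
    Var(v_g)  = n / (n - 1)^3 * sum_i (w_gi - wbar_g)^2,   w_gi = r_gi^2
    lambda*   = min(1, sum_g Var(v_g) / sum_g (v_g - v_median)^2)
    v*_g      = lambda* v_median + (1 - lambda*) v_g
    t*_g      = delta_g / sqrt(v*_g (1/n_A + 1/n_B))

``lambda* = 1`` when the denominator vanishes (all pooled variances equal),
in which case every ``t*`` reduces to the ordinary pooled-variance t computed
with the common variance.  Two-sided p-values come from the Student-t
reference with ``n - 2`` degrees of freedom (a seeded gene-wise permutation
alternative is available for very small groups); q-values are
Benjamini-Hochberg.

Sign convention: ``delta = mean(first-named group) - mean(second-named
group)``; every output table records its contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortLabels, ExpressionMatrix

__all__ = [
    "DETable",
    "shrinkage_t",
    "bh_fdr",
    "call_signature",
    "fisher_enrichment",
    "DifferentialExpression",
    "DifferentialExpressionResults",
]


@dataclass
class DETable:
    """Per-gene differential-expression statistics for one contrast."""

    frame: pd.DataFrame  # columns: delta, v, v_star, t_star, p, q; index: gene ids
    lambda_star: float
    contrast: tuple[str, str]
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0 <= self.lambda_star <= 1:
            raise ValueError("shrinkage intensity outside [0, 1]")
        if (self.frame["v_star"] <= 0).any():
            raise ValueError("non-positive shrunken variance")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _residuals(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True)


def shrinkage_t(
    x: ExpressionMatrix,
    labels: CohortLabels,
    group_a: str,
    group_b: str,
    lambda_override: float | None = None,
    p_method: str = "t",
    n_permutations: int = 1000,
    seed: int = 0,
) -> DETable:
    """Moderated two-sample test of ``group_a`` vs ``group_b`` for every gene.

    Parameters
    ----------
    lambda_override : float in [0, 1], optional
        Fix the shrinkage intensity instead of estimating it; 0 yields the
        ordinary pooled-variance t exactly.
    p_method : {"t", "permutation"}
        Student-t reference with ``n - 2`` df (default), or a seeded
        gene-wise permutation of group membership.
    """
    for grp in (group_a, group_b):
        if grp not in labels.classes:
            raise ValueError(f"unknown group {grp!r}")
    ids_a = [s for s in x.sample_ids if labels.assignments.get(s) == group_a]
    ids_b = [s for s in x.sample_ids if labels.assignments.get(s) == group_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"both groups need >= 2 samples (got {group_a}={len(ids_a)}, {group_b}={len(ids_b)})"
        )
    cols = {s: i for i, s in enumerate(x.sample_ids)}
    xa = x.values[:, [cols[s] for s in ids_a]]
    xb = x.values[:, [cols[s] for s in ids_b]]

    delta, lam, v, v_star, t_star = _shrinkage_t_core(xa, xb, lambda_override)
    n = xa.shape[1] + xb.shape[1]
    bad = np.flatnonzero(v_star == 0)
    if bad.size:
        raise ValueError(
            "shrunken variance is zero (t* undefined) for gene(s): "
            + ", ".join(x.gene_ids[i] for i in bad)
        )

    if p_method == "t":
        p = 2.0 * stats.t.sf(np.abs(t_star), df=n - 2)
    elif p_method == "permutation":
        p = _permutation_p(xa, xb, np.abs(t_star), lambda_override, n_permutations, seed)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    frame = pd.DataFrame(
        {"delta": delta, "v": v, "v_star": v_star, "t_star": t_star, "p": p, "q": bh_fdr(p)},
        index=pd.Index(x.gene_ids, name="gene_id"),
    )
    return DETable(frame, float(lam), (group_a, group_b), xa.shape[1], xb.shape[1])


def _shrinkage_t_core(xa: np.ndarray, xb: np.ndarray, lambda_override: float | None):
    n_a, n_b = xa.shape[1], xb.shape[1]
    n = n_a + n_b
    delta = xa.mean(axis=1) - xb.mean(axis=1)
    r = np.concatenate([_residuals(xa), _residuals(xb)], axis=1)
    v = (r**2).sum(axis=1) / (n - 2)
    v_median = float(np.median(v))
    w = r**2
    var_v = n / (n - 1) ** 3 * ((w - w.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    if lambda_override is not None:
        if not 0 <= lambda_override <= 1:
            raise ValueError("lambda_override must lie in [0, 1]")
        lam = float(lambda_override)
    else:
        denom = float(((v - v_median) ** 2).sum())
        lam = 1.0 if denom == 0 else min(1.0, float(var_v.sum()) / denom)
    v_star = lam * v_median + (1 - lam) * v
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = np.where(v_star > 0, delta / np.sqrt(v_star * (1 / n_a + 1 / n_b)), np.nan)
    t_star = np.where((delta == 0) & (v_star > 0), 0.0, t_star)
    return delta, lam, v, v_star, t_star


def _permutation_p(xa, xb, abs_t_obs, lambda_override, n_permutations, seed):
    """Gene-wise permutation of group membership; add-one two-sided p."""
    rng = np.random.default_rng(int(seed))
    pooled = np.concatenate([xa, xb], axis=1)
    n_a = xa.shape[1]
    exceed = np.ones(pooled.shape[0], dtype=int)  # add-one numerator
    for _ in range(n_permutations):
        perm = rng.permutation(pooled.shape[1])
        pa, pb = pooled[:, perm[:n_a]], pooled[:, perm[n_a:]]
        _, _, _, v_star_p, t_p = _shrinkage_t_core(pa, pb, lambda_override)
        t_p = np.where(v_star_p > 0, t_p, np.inf)
        exceed += (np.abs(t_p) >= abs_t_obs).astype(int)
    return exceed / (1 + n_permutations)


def call_signature(
    tables: list[DETable],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    rule: str = "union",
) -> pd.DataFrame:
    """Call the differential signature across contrasts.

    A gene passes one contrast if ``|delta| > lfc_threshold`` and
    ``q < fdr_threshold``; the signature is the union (default) or
    intersection of passing genes across contrasts.  Output rows are the
    signature genes sorted by gene id, with each contrast's signed fold
    change and pass flag.
    """
    if rule not in ("union", "intersection"):
        raise ValueError(f"unknown rule {rule!r}")
    if not tables:
        raise ValueError("need at least one DE table")
    universe = set(tables[0].gene_ids)
    for t in tables[1:]:
        if set(t.gene_ids) != universe:
            raise ValueError("DE tables cover different gene universes")
    names = [f"{a}_vs_{b}" for a, b in (t.contrast for t in tables)]
    genes = sorted(universe)
    data: dict[str, list] = {}
    passes = np.zeros((len(genes), len(tables)), dtype=bool)
    for j, (t, name) in enumerate(zip(tables, names)):
        fr = t.frame.loc[genes]
        ok = (fr["delta"].abs() > lfc_threshold) & (fr["q"] < fdr_threshold)
        passes[:, j] = ok.to_numpy()
        data[f"delta_{name}"] = fr["delta"].to_numpy()
        data[f"pass_{name}"] = ok.to_numpy()
    selected = passes.any(axis=1) if rule == "union" else passes.all(axis=1)
    out = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    return out.loc[selected]


def fisher_enrichment(
    signature: set[str],
    universe: set[str],
    categories: dict[str, set[str]],
    fdr_threshold: float | None = None,
) -> pd.DataFrame:
    """One-sided over-representation of each category within the signature.

    Per category the 2x2 table (in/out signature x in/out category) over the
    universe is scored with the Fisher exact test, whose one-sided
    over-representation p equals the hypergeometric upper-tail probability.
    Categories are intersected with the universe first; categories empty
    after intersection are skipped with a warning.
    """
    signature = set(signature)
    universe = set(universe)
    offenders = sorted(signature - universe)
    if offenders:
        raise ValueError(f"signature gene(s) outside universe: {', '.join(offenders)}")
    n_univ, n_sig = len(universe), len(signature)
    rows = []
    for name in sorted(categories):
        members = set(categories[name]) & universe
        if not members:
            warnings.warn(f"category {name!r} empty after intersecting the universe; skipped",
                          UserWarning, stacklevel=2)
            continue
        k = len(members & signature)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_sig))
        rows.append((name, k, len(members), n_sig, n_univ, min(p, 1.0)))
    frame = pd.DataFrame(
        rows, columns=["category", "overlap", "category_size", "signature_size", "universe_size", "p"]
    ).set_index("category")
    frame["q"] = bh_fdr(frame["p"].to_numpy()) if len(frame) else np.array([])
    if fdr_threshold is not None:
        frame["enriched"] = frame["q"] < fdr_threshold
    return frame


class DifferentialExpression:
    """Model front-end: shrinkage-t contrasts of one class against others."""

    def __init__(self, x: ExpressionMatrix, labels: CohortLabels):
        self.x = x
        self.labels = labels

    def fit(
        self,
        contrasts: list[tuple[str, str]],
        lambda_override: float | None = None,
        p_method: str = "t",
        n_permutations: int = 1000,
        seed: int = 0,
    ) -> "DifferentialExpressionResults":
        tables = [
            shrinkage_t(self.x, self.labels, a, b, lambda_override, p_method, n_permutations, seed)
            for a, b in contrasts
        ]
        return DifferentialExpressionResults(self, tables)


@dataclass
class DifferentialExpressionResults:
    model: DifferentialExpression
    tables: list[DETable]

    def call_signature(self, lfc_threshold=1.0, fdr_threshold=0.05, rule="union") -> pd.DataFrame:
        return call_signature(self.tables, lfc_threshold, fdr_threshold, rule)

    def summary(self, lfc_threshold=1.0, fdr_threshold=0.05, rule="union") -> str:
        sig = self.call_signature(lfc_threshold, fdr_threshold, rule)
        lines = ["Shrinkage-t differential expression", "==================================="]
        for t in self.tables:
            lines.append(
                f"contrast {t.contrast[0]} vs {t.contrast[1]} "
                f"(n={t.n_a}+{t.n_b}): lambda*={t.lambda_star:.3f}, "
                f"{int((t.frame['q'] < fdr_threshold).sum())} genes at FDR<{fdr_threshold}"
            )
        lines.append(
            f"signature ({rule}, |log2FC|>{lfc_threshold}, FDR<{fdr_threshold}): {len(sig)} genes"
        )
        return "\n".join(lines)
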