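"""Class learnability via label-exchange perturbation of CV accuracy.

The question: does a hypothesized class labeling (say, a putative lymphoma
category next to two established ones) support higher cross-validated
classification accuracy than labelings obtained by exchanging samples between
the putative class and the established ones?  The test

1. estimates the accuracy of the original labeling by repeated stratified
   k-fold cross-validation of a soft-margin linear SVM (all signature genes,
   no feature selection, one-vs-one multiclass reduction, C = 1, gene-wise
   standardization fit on training folds only);
2. enumerates (or uniformly samples) label-exchange perturbations of the
   labeling and scores each with the identical CV protocol;
3. reports the add-one empirical p-value
   ``p = (1 + #{perturbed >= original}) / (1 + N)``.

Exchange schemes
----------------
``three_class_exchange``
    Two samples of the putative class swap labels with one sample of each of
    the two reference classes; all ordered choices are enumerated, giving
    ``n_M (n_M - 1) n_A n_G`` distinct labelings.
``pair_exchange``
    For a two-class labeling, ``n_swaps`` simultaneous cross-class pair
    swaps; distinct labelings correspond to the choice of the swapped subset
    on each side, ``C(n_A, m) C(n_B, m)`` in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import sklearn
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import CohortLabels, ExpressionMatrix

__all__ = [
    "CVResult",
    "RelabelingResult",
    "cross_validated_accuracy",
    "enumerate_relabelings",
    "relabeling_test",
    "merge_classes",
    "LearnabilityTest",
    "LearnabilityResults",
]


@dataclass
class CVResult:
    """Repeated stratified cross-validation accuracies."""

    fold_accuracies: np.ndarray  # reps x folds
    mean_accuracy: float
    reps: int
    folds: int
    seed: int

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        if self.fold_accuracies.shape != (self.reps, self.folds):
            raise ValueError("fold_accuracies shape must be (reps, folds)")
        if np.any((self.fold_accuracies < 0) | (self.fold_accuracies > 1)):
            raise ValueError("fold accuracies outside [0, 1]")


@dataclass
class RelabelingResult:
    """Outcome of the label-exchange learnability test."""

    original_accuracy: float
    perturbed_accuracies: np.ndarray
    n_enumerated_total: int
    exhaustive: bool
    p_empirical: float
    scheme: str

    def __post_init__(self) -> None:
        self.perturbed_accuracies = np.asarray(self.perturbed_accuracies, dtype=float)
        n = len(self.perturbed_accuracies)
        if self.exhaustive and n != self.n_enumerated_total:
            raise ValueError("exhaustive result must carry all enumerated labelings")
        if not 0 < self.p_empirical <= 1:
            raise ValueError("empirical p must lie in (0, 1]")


def _class_sizes_checked(labels: CohortLabels, folds: int) -> None:
    for cls, size in labels.class_sizes().items():
        if size < folds:
            raise ValueError(
                f"class {cls!r} has {size} samples, fewer than the {folds} CV folds"
            )


def _encode(labels_vec: np.ndarray, classes: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[v] for v in labels_vec], dtype=int)


def _cv_correct_counts(
    X: np.ndarray, y: np.ndarray, folds: int, reps: int, seed: int
) -> tuple[int, np.ndarray]:
    """Total correct held-out predictions over all reps, plus per-fold accuracies.

    The per-rep fold assignment is stratified and derived deterministically
    from ``seed`` and the repetition index.
    """
    fold_acc = np.empty((reps, folds))
    total_correct = 0
    # inputs validated upstream; skipping sklearn's per-fit re-validation keeps
    # the ~10^6-fit relabeling enumerations tractable
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for rep in range(reps):
            rep_seed = int(
                np.random.SeedSequence(seed, spawn_key=(rep,)).generate_state(1)[0] % (2**31)
            )
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
            for fi, (train, test) in enumerate(skf.split(X, y)):
                Xtr, Xte = X[train], X[test]
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0)
                sd[sd == 0] = 1.0
                clf = SVC(kernel="linear", C=1.0)
                clf.fit((Xtr - mu) / sd, y[train])
                pred = clf.predict((Xte - mu) / sd)
                n_correct = int(np.sum(pred == y[test]))
                total_correct += n_correct
                fold_acc[rep, fi] = n_correct / len(test)
    return total_correct, fold_acc


def cross_validated_accuracy(
    x: ExpressionMatrix,
    labels: CohortLabels,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold accuracy of a linear SVM on all genes.

    The classifier uses every gene of the supplied matrix (no feature
    selection); accuracy is pooled over held-out folds within a repetition
    and averaged over repetitions.
    """
    if folds < 2 or reps < 2:
        raise ValueError("folds and reps must both be >= 2")
    if len(labels.classes) < 2:
        raise ValueError("need at least 2 classes")
    _class_sizes_checked(labels, folds)
    X = np.ascontiguousarray(x.values.T, dtype=float)
    if np.ptp(X) == 0:
        raise ValueError("constant feature matrix: no gene varies across samples")
    y = _encode(labels.label_vector(x.sample_ids), labels.classes)
    total_correct, fold_acc = _cv_correct_counts(X, y, folds, reps, int(seed))
    mean_acc = total_correct / (reps * x.n_samples)
    return CVResult(fold_acc, float(mean_acc), reps, folds, int(seed))


def _sample_without_replacement(n_total: int, size: int, rng: np.random.Generator) -> np.ndarray:
    if n_total <= 10**7:
        return rng.choice(n_total, size=size, replace=False)
    chosen: set[int] = set()  # Floyd's algorithm for huge index spaces
    for j in range(n_total - size, n_total):
        t = int(rng.integers(0, j + 1))
        chosen.add(t if t not in chosen else j)
    return np.array(sorted(chosen))


def _unrank_combination(idx: int, n: int, m: int) -> list[int]:
    """Lexicographic unranking of the idx-th m-subset of range(n)."""
    out: list[int] = []
    x = 0
    for pos in range(m):
        for v in range(x, n):
            block = comb(n - v - 1, m - pos - 1)
            if idx < block:
                out.append(v)
                x = v + 1
                break
            idx -= block
    return out


def enumerate_relabelings(
    labels: CohortLabels,
    scheme: str = "three_class_exchange",
    roles: tuple[str, str, str] | tuple[str, str] | None = None,
    n_swaps: int = 1,
    cap: int = 10_000,
    seed: int = 0,
) -> tuple[list[np.ndarray], int, bool]:
    """Enumerate label-exchange perturbations of a labeling.

    Returns ``(labelings, n_total, exhaustive)`` where each labeling is a
    label vector aligned to ``labels.sample_ids``.  If the number of distinct
    labelings exceeds ``cap``, a seeded uniform sample of ``cap`` distinct
    labelings is drawn instead and ``exhaustive`` is False.

    ``roles`` names the classes taking part: for ``three_class_exchange`` the
    (putative, first-reference, second-reference) classes — by default the
    label set's first three classes in order; for ``pair_exchange`` the two
    classes, by default the only two present.
    """
    ids = labels.sample_ids
    vec = labels.label_vector(ids)

    if scheme == "three_class_exchange":
        if roles is None:
            if len(labels.classes) < 3:
                raise ValueError("three_class_exchange needs three classes (or explicit roles)")
            roles = tuple(labels.classes[:3])  # type: ignore[assignment]
        role_m, role_a, role_g = roles  # type: ignore[misc]
        for r in (role_m, role_a, role_g):
            if r not in labels.classes:
                raise ValueError(f"role class {r!r} not present in labels")
        m_idx = [i for i, v in enumerate(vec) if v == role_m]
        a_idx = [i for i, v in enumerate(vec) if v == role_a]
        g_idx = [i for i, v in enumerate(vec) if v == role_g]
        n_m, n_a, n_g = len(m_idx), len(a_idx), len(g_idx)
        if n_m < 2:
            raise ValueError(
                f"three_class_exchange needs >= 2 samples of {role_m!r}, got {n_m}"
            )
        if n_a < 1 or n_g < 1:
            raise ValueError("three_class_exchange needs >= 1 sample in each reference class")
        n_total = n_m * (n_m - 1) * n_a * n_g

        def build(index: int) -> np.ndarray:
            rem, i4 = divmod(index, n_g)
            rem, i3 = divmod(rem, n_a)
            i1, i2 = divmod(rem, n_m - 1)
            m1 = m_idx[i1]
            others = m_idx[:i1] + m_idx[i1 + 1 :]
            m2 = others[i2]
            a, g = a_idx[i3], g_idx[i4]
            out = vec.copy()
            out[m1], out[a] = role_a, role_m
            out[m2], out[g] = role_g, role_m
            return out

    elif scheme == "pair_exchange":
        if roles is None:
            if len(labels.classes) != 2:
                raise ValueError("pair_exchange needs exactly two classes (or explicit roles)")
            roles = tuple(labels.classes)  # type: ignore[assignment]
        role_a, role_b = roles  # type: ignore[misc]
        a_idx = [i for i, v in enumerate(vec) if v == role_a]
        b_idx = [i for i, v in enumerate(vec) if v == role_b]
        n_a, n_b = len(a_idx), len(b_idx)
        if not 1 <= n_swaps <= min(n_a, n_b):
            raise ValueError(
                f"n_swaps={n_swaps} outside 1..min(n_A={n_a}, n_B={n_b})"
            )
        c_b = comb(n_b, n_swaps)
        n_total = comb(n_a, n_swaps) * c_b

        def build(index: int) -> np.ndarray:
            ia, ib = divmod(index, c_b)
            sub_a = _unrank_combination(ia, n_a, n_swaps)
            sub_b = _unrank_combination(ib, n_b, n_swaps)
            out = vec.copy()
            for j in sub_a:
                out[a_idx[j]] = role_b
            for j in sub_b:
                out[b_idx[j]] = role_a
            return out

    else:
        raise ValueError(f"unknown relabeling scheme {scheme!r}")

    if n_total <= cap:
        indices = np.arange(n_total)
        exhaustive = True
    else:
        rng = np.random.default_rng(int(seed))
        indices = _sample_without_replacement(n_total, cap, rng)
        exhaustive = False
    return [build(int(i)) for i in indices], n_total, exhaustive


def merge_classes(labels: CohortLabels, source: str, target: str) -> CohortLabels:
    """Relabel every ``source`` sample as ``target`` (class list updated)."""
    if source == target:
        raise ValueError("source and target classes must differ")
    for lab in (source, target):
        if lab not in labels.classes:
            raise ValueError(f"unknown class label {lab!r}")
    merged = {s: (target if c == source else c) for s, c in labels.assignments.items()}
    return CohortLabels(merged, classes=[c for c in labels.classes if c != source])


def relabeling_test(
    x: ExpressionMatrix,
    labels: CohortLabels,
    scheme: str = "three_class_exchange",
    roles=None,
    n_swaps: int = 1,
    folds: int = 10,
    reps: int = 10,
    cap: int = 10_000,
    seed: int = 0,
) -> RelabelingResult:
    """Label-exchange permutation test of CV accuracy.

    The original labeling and every perturbed labeling are scored with the
    identical repeated-CV protocol (same fold-assignment seed rule), and the
    add-one empirical p-value compares the original accuracy with the
    perturbed distribution.
    """
    if folds < 2 or reps < 2:
        raise ValueError("folds and reps must both be >= 2")
    if len(labels.classes) < 2:
        raise ValueError("need at least 2 classes")
    _class_sizes_checked(labels, folds)
    X = np.ascontiguousarray(x.values.T, dtype=float)
    if np.ptp(X) == 0:
        raise ValueError("constant feature matrix: no gene varies across samples")
    ids = x.sample_ids
    classes = labels.classes
    ss = np.random.SeedSequence(int(seed), spawn_key=(0xC7,))
    cv_seed, enum_seed = (int(v % (2**31)) for v in ss.generate_state(2))

    y0 = _encode(labels.label_vector(ids), classes)
    orig_correct, _ = _cv_correct_counts(X, y0, folds, reps, cv_seed)

    aligned = labels.restrict(ids)
    labelings, n_total, exhaustive = enumerate_relabelings(
        aligned, scheme=scheme, roles=roles, n_swaps=n_swaps, cap=cap, seed=enum_seed
    )
    denom = reps * x.n_samples
    perturbed_counts = np.empty(len(labelings), dtype=int)
    for i, lab_vec in enumerate(labelings):
        yi = _encode(lab_vec, classes)
        perturbed_counts[i], _ = _cv_correct_counts(X, yi, folds, reps, cv_seed)

    n = len(labelings)
    # integer comparison of correct counts: numerically exact >= semantics
    p = (1 + int(np.sum(perturbed_counts >= orig_correct))) / (1 + n)
    return RelabelingResult(
        original_accuracy=orig_correct / denom,
        perturbed_accuracies=perturbed_counts / denom,
        n_enumerated_total=n_total,
        exhaustive=exhaustive,
        p_empirical=float(p),
        scheme=scheme,
    )


class LearnabilityTest:
    """Model front-end: is a class labeling learnable beyond label exchange?

    Parameters
    ----------
    x : ExpressionMatrix
        Signature-restricted expression matrix.
    labels : CohortLabels
        Hypothesized class labeling.
    scheme : {"three_class_exchange", "pair_exchange"}
    roles : tuple of class labels, optional
        Role assignment for the scheme (see :func:`enumerate_relabelings`).
    """

    def __init__(self, x, labels, scheme="three_class_exchange", roles=None, n_swaps=1):
        self.x = x
        self.labels = labels
        self.scheme = scheme
        self.roles = roles
        self.n_swaps = n_swaps

    def fit(self, folds: int = 10, reps: int = 10, cap: int = 10_000, seed: int = 0):
        result = relabeling_test(
            self.x,
            self.labels,
            scheme=self.scheme,
            roles=self.roles,
            n_swaps=self.n_swaps,
            folds=folds,
            reps=reps,
            cap=cap,
            seed=seed,
        )
        return LearnabilityResults(self, result, folds, reps, seed)


@dataclass
class LearnabilityResults:
    model: LearnabilityTest
    result: RelabelingResult
    folds: int
    reps: int
    seed: int

    @property
    def p_value(self) -> float:
        return self.result.p_empirical

    @property
    def original_accuracy(self) -> float:
        return self.result.original_accuracy

    def summary(self) -> str:
        r = self.result
        lines = [
            "Label-exchange learnability test",
            "================================",
            f"scheme:               {r.scheme}",
            f"CV protocol:          {self.reps} x {self.folds}-fold, linear SVM (C=1)",
            f"original accuracy:    {r.original_accuracy:.4f}",
            f"perturbed labelings:  {len(r.perturbed_accuracies)}"
            + ("" if r.exhaustive else f" (sampled of {r.n_enumerated_total})"),
            f"perturbed acc median: {float(np.median(r.perturbed_accuracies)):.4f}",
            f"empirical p-value:    {r.p_empirical:.6g}",
        ]
        return "\n".join(lines)

    def plot_histogram(self, ax=None):
        """Histogram of perturbed accuracies with the original marked in red."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        r = self.result
        ax.hist(r.perturbed_accuracies, bins=30, color="0.6")
        ax.axvline(r.original_accuracy, color="tab:red", lw=2)
        ax.set_xlabel("cross-validated accuracy")
        ax.set_ylabel("perturbed labelings")
        ax.set_title(f"p = {r.p_empirical:.3g}")
        return ax
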