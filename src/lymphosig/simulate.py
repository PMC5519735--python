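"""Synthetic expression cohorts with planted class structure.

The generator emulates the statistical structure the downstream analyses
assume of a post-normalization microarray cohort: per-gene Gaussian noise on
the log2 scale, gene-specific baselines, a designated signature subset of
genes carrying class-specific mean shifts, and optional additive batch
effects.  The model for sample ``s`` and gene ``g`` is

    x_gs = mu_g + delta[class(s), g] * 1[g in signature] + b_batch(s) + eps_gs

with ``mu_g ~ Uniform(4, 12)`` (the span of log2 microarray intensities),
``eps_gs ~ Normal(0, sigma_g^2)``, ``sigma_g ~ Uniform(noise_sd_range)`` and
``b ~ Normal(0, batch_sd^2)``.  Everything is reproducible from the
``SyntheticSpec`` seed; independent named sub-streams are derived for baselines, noise scales,
batch effects and residuals so that, e.g., disabling batches does not shift
the residual draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CohortLabels, ExpressionMatrix, GeneSignature

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_cohort",
    "null_relabel",
    "block_effect_matrix",
    "rotation_effect_matrix",
]

_SUBSTREAMS = ("baseline", "noise_sd", "batch", "residual", "batch_assign")


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(_SUBSTREAMS.index(name),)))


def block_effect_matrix(n_classes: int, signature_size: int, delta: float) -> np.ndarray:
    """Effect matrix giving each class a +delta shift on its own gene block.

    The signature genes are split into ``n_classes`` contiguous, near-equal
    blocks; class ``j`` is shifted by ``delta`` on block ``j`` and unshifted
    elsewhere, so every class pair differs on two blocks.
    """
    if n_classes < 1 or signature_size < n_classes:
        raise ValueError("need signature_size >= n_classes >= 1")
    effects = np.zeros((n_classes, signature_size))
    bounds = np.linspace(0, signature_size, n_classes + 1).astype(int)
    for j in range(n_classes):
        effects[j, bounds[j] : bounds[j + 1]] = delta
    return effects


def rotation_effect_matrix(n_classes: int, signature_size: int, delta: float) -> np.ndarray:
    """Effect matrix separating every class pair on every signature gene.

    Gene ``g`` assigns the levels ``0, delta, ..., (n_classes-1)*delta`` to
    the classes in a rotating pattern, so each pair of classes differs by at
    least ``delta`` on each signature gene and all pairwise mean-profile
    distances are equal by symmetry.
    """
    if n_classes < 1 or signature_size < 1:
        raise ValueError("need n_classes >= 1 and signature_size >= 1")
    c = np.arange(n_classes)[:, None]
    g = np.arange(signature_size)[None, :]
    return delta * ((c + g) % n_classes)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    classes : list of (label, n_samples)
        Sample classes and their sizes, in output order.
    n_genes : int
        Total number of genes; the first ``signature_size`` are the signature.
    signature_size : int
        Number of signature genes carrying class-specific shifts.
    effect_matrix : ndarray, shape (n_classes, signature_size)
        Mean shift (log2 units) of each class on each signature gene.
    noise_sd_range : (float, float)
        Bounds of the uniform distribution of gene-specific noise SDs.
    batch : (n_batches, batch_sd) or None
        Optional additive batch effect.
    batch_confounded : bool
        If True, batches are assigned by class blocks (batch correlated with
        class); otherwise samples are rotated through batches within class.
    seed : int
        Seed of the cohort's RNG streams.
    """

    classes: list[tuple[str, int]]
    n_genes: int
    signature_size: int
    effect_matrix: np.ndarray
    noise_sd_range: tuple[float, float] = (0.5, 1.5)
    batch: tuple[int, float] | None = None
    batch_confounded: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_matrix = np.atleast_2d(np.asarray(self.effect_matrix, dtype=float))
        if not self.classes:
            raise ValueError("at least one class is required")
        labels = [c for c, _ in self.classes]
        if len(set(labels)) != len(labels):
            raise ValueError("class labels must be distinct")
        if any(n < 1 for _, n in self.classes):
            raise ValueError("every class needs at least one sample")
        if not (1 <= self.signature_size <= self.n_genes):
            raise ValueError("need 1 <= signature_size <= n_genes")
        if self.effect_matrix.shape != (len(self.classes), self.signature_size):
            raise ValueError(
                f"effect_matrix shape {self.effect_matrix.shape} != "
                f"({len(self.classes)}, {self.signature_size})"
            )
        lo, hi = self.noise_sd_range
        if not (0 < lo <= hi):
            raise ValueError("noise_sd_range bounds must be positive with lo <= hi")
        if self.batch is not None:
            n_batches, batch_sd = self.batch
            if n_batches < 1 or batch_sd < 0:
                raise ValueError("batch needs n_batches >= 1 and batch_sd >= 0")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.classes)

    @classmethod
    def planted(
        cls,
        n_classes: int = 3,
        samples_per_class: int = 12,
        n_genes: int = 100,
        delta: float = 4.0,
        sigma: float = 0.5,
        signature_fraction: float = 0.3,
        seed: int = 0,
        class_labels: list[str] | None = None,
        layout: str = "blocks",
    ) -> "SyntheticSpec":
        """Planted-class cohort with effects on a signature subset of genes.

        The signature covers ``signature_fraction`` of all genes, mirroring
        signature-restricted panels where a minority of probes carries the
        class contrast; every gene has noise SD ``sigma``.  ``layout``
        chooses the effect pattern: ``"blocks"`` shifts each class by
        ``delta`` on its own contiguous block of signature genes (distinct
        marker sets per class), ``"rotation"`` separates every class pair by
        at least ``delta`` on every signature gene
        (:func:`rotation_effect_matrix`).  ``delta = 0`` yields a
        structureless null cohort.
        """
        labels = class_labels or [f"C{i + 1}" for i in range(n_classes)]
        if len(labels) != n_classes:
            raise ValueError("class_labels length must equal n_classes")
        signature_size = max(n_classes, int(round(signature_fraction * n_genes)))
        if layout == "blocks":
            effects = block_effect_matrix(n_classes, signature_size, delta)
        elif layout == "rotation":
            effects = rotation_effect_matrix(n_classes, signature_size, delta)
        else:
            raise ValueError(f"unknown effect layout {layout!r}")
        return cls(
            classes=[(lab, samples_per_class) for lab in labels],
            n_genes=n_genes,
            signature_size=signature_size,
            effect_matrix=effects,
            noise_sd_range=(sigma, sigma),
            seed=seed,
        )


@dataclass
class SyntheticCohort:
    """A generated cohort: matrix, labels, planted truth and batch map."""

    matrix: ExpressionMatrix
    labels: CohortLabels
    truth: set[tuple[str, str]]  # (gene_id, class label) with nonzero planted effect
    batch_of: dict[str, int]
    signature_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.matrix.sample_ids) != set(self.labels.sample_ids):
            raise ValueError("matrix and labels cover different sample sets")
        sig = set(self.signature_genes)
        if any(g not in sig for g, _ in self.truth):
            raise ValueError("planted truth refers to non-signature genes")

    @property
    def signature(self) -> GeneSignature:
        return GeneSignature(list(self.signature_genes), name="planted-signature")

    _delta: dict[tuple[str, str], float] = field(default_factory=dict, repr=False)

    def true_de_genes(self, class_a: str, class_b: str) -> set[str]:
        """Genes whose planted shift differs between two classes."""
        return {
            g
            for g in self.signature_genes
            if self._delta.get((g, class_a), 0.0) != self._delta.get((g, class_b), 0.0)
        }


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Draw a cohort from a :class:`SyntheticSpec`; bit-reproducible from its seed."""
    g, s = spec.n_genes, spec.n_samples
    gene_ids = [f"g{i + 1:04d}" for i in range(g)]
    sample_ids: list[str] = []
    class_of: list[int] = []
    for ci, (label, n) in enumerate(spec.classes):
        for j in range(n):
            sample_ids.append(f"{label}_{j + 1:02d}")
            class_of.append(ci)
    class_idx = np.array(class_of)

    mu = _substream(spec.seed, "baseline").uniform(4.0, 12.0, size=g)
    lo, hi = spec.noise_sd_range
    sigma = _substream(spec.seed, "noise_sd").uniform(lo, hi, size=g)
    eps = _substream(spec.seed, "residual").standard_normal((g, s)) * sigma[:, None]

    values = mu[:, None] + eps
    shifts = np.zeros((g, s))
    shifts[: spec.signature_size, :] = spec.effect_matrix[class_idx, :].T
    values += shifts

    batch_of: dict[str, int] = {}
    if spec.batch is not None:
        n_batches, batch_sd = spec.batch
        if spec.batch_confounded:
            # class blocks map onto batches: batch id follows class id
            assign = class_idx % n_batches
        else:
            # rotate through batches within each class: balanced design
            assign = np.empty(s, dtype=int)
            for ci in range(len(spec.classes)):
                members = np.flatnonzero(class_idx == ci)
                assign[members] = np.arange(members.size) % n_batches
        b = _substream(spec.seed, "batch").normal(0.0, batch_sd, size=n_batches)
        values = values + b[assign][None, :]
        batch_of = {sid: int(a) for sid, a in zip(sample_ids, assign)}
    else:
        batch_of = {sid: 0 for sid in sample_ids}

    matrix = ExpressionMatrix(values, gene_ids, sample_ids)
    labels = CohortLabels(
        {sid: spec.classes[ci][0] for sid, ci in zip(sample_ids, class_of)},
        classes=[c for c, _ in spec.classes],
    )
    signature_genes = gene_ids[: spec.signature_size]
    truth = {
        (gene_ids[gj], spec.classes[ci][0])
        for ci in range(len(spec.classes))
        for gj in range(spec.signature_size)
        if spec.effect_matrix[ci, gj] != 0.0
    }
    cohort = SyntheticCohort(matrix, labels, truth, batch_of, signature_genes)
    cohort._delta = {
        (gene_ids[gj], spec.classes[ci][0]): float(spec.effect_matrix[ci, gj])
        for ci in range(len(spec.classes))
        for gj in range(spec.signature_size)
    }
    return cohort


def null_relabel(cohort: SyntheticCohort, seed: int) -> CohortLabels:
    """Uniformly random permutation of the label vector (class sizes preserved)."""
    rng = np.random.default_rng(int(seed))
    ids = cohort.labels.sample_ids
    vec = cohort.labels.label_vector()
    return cohort.labels.with_vector(vec[rng.permutation(len(ids))], ids)
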