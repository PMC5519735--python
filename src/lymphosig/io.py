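"""Cohort tabular formats and signature restriction.

All analyses in this package operate on an already-normalized log2 expression
matrix with genes (probes) in rows and samples in columns — the orientation of
expression deposits.  Identifier matching is exact string equality at the probe
level; no probe-to-gene collapsing is performed.

File formats
------------
Expression TSV
    Header line ``gene_id<TAB>sample1<TAB>...``; one row per gene, first column
    the gene identifier, remaining cells numeric log2 intensities.
Label TSV
    Two columns ``sample_id<TAB>class``, no header required (a header line is
    tolerated if its first field is ``sample_id``).
Signature list
    One identifier per line; ``#`` starts a comment; blank lines ignored.
"""

from __future__ import annotations

import os
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CohortLabels",
    "GeneSignature",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_signature",
    "subset_by_signature",
]


def _find_duplicates(items) -> list[str]:
    return sorted(name for name, n in Counter(items).items() if n > 1)


@dataclass
class ExpressionMatrix:
    """Log2 expression values, ``G`` genes x ``S`` samples.

    Parameters
    ----------
    values : ndarray, shape (G, S)
        Finite log2-scale intensities.
    gene_ids : list of str
        Unique row identifiers (probes or genes).
    sample_ids : list of str
        Unique column identifiers; at least two samples.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        g, s = self.values.shape
        if g < 1:
            raise ValueError("expression matrix needs at least one gene")
        if s < 2:
            raise ValueError(f"expression matrix needs at least 2 samples, got {s}")
        if len(self.gene_ids) != g or len(self.sample_ids) != s:
            raise ValueError(
                f"identifier lengths ({len(self.gene_ids)} genes, "
                f"{len(self.sample_ids)} samples) do not match matrix shape {g}x{s}"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {kind} identifier(s): {', '.join(dups)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample(s): {', '.join(missing)}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), list(sample_ids))


@dataclass
class CohortLabels:
    """Sample-to-class assignment over a finite, ordered label set."""

    assignments: dict[str, str]
    classes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}
        if not self.assignments:
            raise ValueError("label set is empty")
        seen: list[str] = []
        for lab in self.assignments.values():
            if lab not in seen:
                seen.append(lab)
        if self.classes is None:
            self.classes = seen
        else:
            self.classes = [str(c) for c in self.classes]
            if sorted(self.classes) != sorted(seen):
                raise ValueError(
                    "declared classes do not match the labels present: "
                    f"{self.classes} vs {seen}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    @property
    def n_samples(self) -> int:
        return len(self.assignments)

    def class_sizes(self) -> dict[str, int]:
        sizes = Counter(self.assignments.values())
        return {c: sizes[c] for c in self.classes}

    def samples_of(self, label: str) -> list[str]:
        if label not in self.classes:
            raise KeyError(f"unknown class label {label!r}")
        return [s for s, c in self.assignments.items() if c == label]

    def label_vector(self, sample_ids: list[str] | None = None) -> np.ndarray:
        ids = self.sample_ids if sample_ids is None else sample_ids
        return np.array([self.assignments[s] for s in ids], dtype=object)

    def with_vector(self, labels, sample_ids: list[str] | None = None) -> "CohortLabels":
        ids = self.sample_ids if sample_ids is None else sample_ids
        return CohortLabels(dict(zip(ids, (str(x) for x in labels))))

    def restrict(self, sample_ids: list[str]) -> "CohortLabels":
        return CohortLabels({s: self.assignments[s] for s in sample_ids})


@dataclass
class GeneSignature:
    """Ordered list of gene/probe identifiers defining an analysis panel."""

    gene_ids: list[str]
    name: str = "signature"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        if not self.gene_ids:
            raise ValueError("gene signature is empty")
        dups = _find_duplicates(self.gene_ids)
        if dups:
            raise ValueError(f"duplicate signature gene(s): {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self.gene_ids)


def read_expression_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes-x-samples expression TSV.

    The first header field names the gene-id column and is ignored; remaining
    header fields are the sample ids.  Row and column order are preserved.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        dups = _find_duplicates(sample_ids)
        if dups:
            raise ValueError(f"{path}: duplicate sample identifier(s): {', '.join(dups)}")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {len(sample_ids) + 1}"
                )
            gene_ids.append(fields[0])
            row = []
            for col, cell in enumerate(fields[1:]):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at line {lineno} "
                        f"(gene {fields[0]!r}), column {sample_ids[col]!r}"
                    ) from None
            rows.append(row)
    dups = _find_duplicates(gene_ids)
    if dups:
        raise ValueError(f"{path}: duplicate gene identifier(s): {', '.join(dups)}")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return ExpressionMatrix(np.array(rows, dtype=float), gene_ids, sample_ids)


def write_expression_matrix(x: ExpressionMatrix, path) -> None:
    """Write a TSV that round-trips bit-identically (17 significant digits)."""
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(x.sample_ids) + "\n")
        for g, row in zip(x.gene_ids, x.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_labels(path) -> CohortLabels:
    """Read a two-column sample/class TSV; classes ordered by first appearance."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
            sample, label = fields
            if lineno == 1 and sample == "sample_id":
                continue
            if sample in assignments:
                raise ValueError(f"{path}: sample {sample!r} listed twice (line {lineno})")
            assignments[sample] = label
    if not assignments:
        raise ValueError(f"{path}: no label rows")
    return CohortLabels(assignments)


def write_labels(labels: CohortLabels, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tclass\n")
        for sample, label in labels.assignments.items():
            fh.write(f"{sample}\t{label}\n")


def read_signature(path, name: str | None = None) -> GeneSignature:
    """Read a one-identifier-per-line gene list; ``#`` comments allowed."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            entry = line.split("#", 1)[0].strip()
            if entry:
                genes.append(entry)
    if not genes:
        raise ValueError(f"{path}: signature file contains no gene identifiers")
    return GeneSignature(genes, name=name or os.path.basename(str(path)))


def subset_by_signature(x: ExpressionMatrix, sig: GeneSignature) -> ExpressionMatrix:
    """Restrict a matrix to signature genes, in signature order.

    Signature genes absent from the matrix are dropped with a warning; zero
    overlap is an error.  Idempotent: applying the restriction twice equals
    applying it once.
    """
    index = {g: i for i, g in enumerate(x.gene_ids)}
    present = [g for g in sig.gene_ids if g in index]
    missing = [g for g in sig.gene_ids if g not in index]
    if not present:
        raise ValueError(
            f"no overlap between signature {sig.name!r} ({len(sig)} genes) and matrix genes"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from matrix: {', '.join(missing)}",
            UserWarning,
            stacklevel=2,
        )
    rows = [index[g] for g in present]
    return ExpressionMatrix(x.values[rows, :], present, list(x.sample_ids))
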