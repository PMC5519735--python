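"""End-to-end orchestration: simulate -> restrict -> cluster stability ->
learnability -> differential expression -> enrichment.

A run is described by a flat key-value :class:`RunConfig` (see
:meth:`RunConfig.from_file`), executes the enabled stages in order on the
signature-restricted matrix, and writes every stage artifact plus a JSON run
report into the output directory.  One global seed governs the run;
per-stage seeds are derived by hashing ``"<seed>:<stage name>"`` so that
toggling one stage never shifts another stage's random stream.  Two runs
with identical config and seed produce bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .de import DifferentialExpression, fisher_enrichment
from .io import (
    CohortLabels,
    ExpressionMatrix,
    GeneSignature,
    read_expression_matrix,
    read_labels,
    read_signature,
    subset_by_signature,
    write_expression_matrix,
    write_labels,
)
from .learnability import LearnabilityTest, merge_classes
from .simulate import SyntheticSpec, block_effect_matrix, generate_cohort
from .stability import ClusterStability

__all__ = ["RunConfig", "RunReport", "validate_config", "run_full_analysis", "stage_seed"]

_STAGES = ("simulate", "stability", "learnability", "de", "enrich")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: first 4 bytes of sha256('<seed>:<stage>')."""
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Flat configuration of a full analysis run."""

    # input mode and paths
    mode: str = "synthetic"  # "synthetic" or "files"
    expr: str | None = None
    labels: str | None = None
    signature: str | None = None
    categories: str | None = None
    outdir: str = "lymphosig_run"
    seed: int = 0
    # stage toggles
    run_stability: bool = True
    run_learnability: bool = True
    run_de: bool = True
    run_enrich: bool = False
    # synthetic cohort
    classes: list[tuple[str, int]] = field(
        default_factory=lambda: [("MZBL", 12), ("ABC", 12), ("GCB", 12)]
    )
    n_genes: int = 300
    signature_size: int = 60
    delta: float = 2.0
    noise_lo: float = 0.5
    noise_hi: float = 1.0
    n_batches: int = 0
    batch_sd: float = 0.0
    batch_confounded: bool = False
    # stability
    k_min: int = 2
    k_max: int = 6
    resamples: int = 50
    subsample_fraction: float = 0.8
    restarts: int = 10
    alpha: float = 0.05
    # learnability
    scheme: str = "three_class_exchange"
    roles: list[str] | None = None
    merge_source: str | None = None  # two-class variant: merge then pair_exchange
    merge_target: str | None = None
    n_swaps: int = 1
    folds: int = 5
    reps: int = 5
    cap: int = 10_000
    # differential expression
    contrasts: list[tuple[str, str]] | None = None
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    rule: str = "union"

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` text file (# comments allowed).

        Composite values: ``classes = MZBL:12,ABC:12,GCB:12``;
        ``contrasts = MZBL:ABC,MZBL:GCB``; ``roles = MZBL,ABC,GCB``.
        Keyword overrides (e.g. from CLI flags) win over file values.
        """
        raw: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            raw[key] = value
        kwargs: dict = {}
        valid = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in valid:
                raise ValueError(f"{path}: unknown config key {key!r}")
            kwargs[key] = _parse_value(key, value)
        kwargs.update(overrides)
        return cls(**kwargs)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out["classes"] = [list(c) for c in self.classes]
        if self.contrasts:
            out["contrasts"] = [list(c) for c in self.contrasts]
        return out


def _parse_value(key: str, value: str):
    if key == "classes":
        pairs = [tok.split(":") for tok in value.split(",") if tok.strip()]
        return [(name.strip(), int(n)) for name, n in pairs]
    if key == "contrasts":
        pairs = [tok.split(":") for tok in value.split(",") if tok.strip()]
        return [(a.strip(), b.strip()) for a, b in pairs]
    if key == "roles":
        return [tok.strip() for tok in value.split(",") if tok.strip()]
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    if value.lower() in ("none", ""):
        return None
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


def validate_config(config: RunConfig) -> list[str]:
    """Collect every configuration problem (empty list means runnable)."""
    problems: list[str] = []
    if config.mode not in ("synthetic", "files"):
        problems.append(f"unknown mode {config.mode!r}")
    if config.mode == "files":
        for name in ("expr", "labels"):
            path = getattr(config, name)
            if path is None:
                problems.append(f"mode 'files' requires the {name} path")
            elif not Path(path).exists():
                problems.append(f"{name} path does not exist: {path}")
        for name in ("signature", "categories"):
            path = getattr(config, name)
            if path is not None and not Path(path).exists():
                problems.append(f"{name} path does not exist: {path}")
        sizes = None
        if not any(p.startswith("labels") for p in problems) and config.labels:
            try:
                sizes = read_labels(config.labels).class_sizes()
            except Exception as exc:  # surfaced as a problem, not a crash
                problems.append(f"labels unreadable: {exc}")
    else:
        if not config.classes:
            problems.append("synthetic mode needs at least one class")
        if any(n < 1 for _, n in config.classes):
            problems.append("every synthetic class needs >= 1 sample")
        if not 1 <= config.signature_size <= config.n_genes:
            problems.append("need 1 <= signature_size <= n_genes")
        if not 0 < config.noise_lo <= config.noise_hi:
            problems.append("need 0 < noise_lo <= noise_hi")
        sizes = dict(config.classes)
    if sizes and config.run_learnability:
        small = {c: n for c, n in sizes.items() if n < config.folds}
        for cls, n in small.items():
            problems.append(
                f"class {cls!r} has {n} samples, fewer than folds={config.folds}"
            )
    if config.run_stability:
        if config.k_min < 1 or config.k_max < config.k_min:
            problems.append(f"bad k range [{config.k_min}, {config.k_max}]")
        if not 0.5 <= config.subsample_fraction < 1:
            problems.append("subsample_fraction must lie in [0.5, 1)")
        if config.resamples < 10:
            problems.append("resamples must be >= 10")
    if config.lfc_threshold < 0:
        problems.append("lfc_threshold must be >= 0")
    if not 0 < config.fdr_threshold < 1:
        problems.append("fdr_threshold must lie in (0, 1)")
    if config.rule not in ("union", "intersection"):
        problems.append(f"unknown signature rule {config.rule!r}")
    if config.scheme not in ("three_class_exchange", "pair_exchange"):
        problems.append(f"unknown relabeling scheme {config.scheme!r}")
    if config.run_enrich and config.categories is None:
        problems.append("enrichment stage needs a categories path")
    return problems


@dataclass
class RunReport:
    """Per-stage status and headline results of one pipeline run."""

    stages: dict[str, str] = field(default_factory=dict)  # stage -> ok/skipped/failed
    results: dict = field(default_factory=dict)
    elapsed: dict[str, float] = field(default_factory=dict)
    version: str = __version__
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _log(message: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] {message}", file=sys.stderr)


def _read_categories(path) -> dict[str, set[str]]:
    categories: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        category, gene = line.split("\t")
        categories.setdefault(category, set()).add(gene)
    return categories


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order; write artifacts and the report.

    Any stage failure aborts the run with the stage name after writing the
    partial report.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.echo())
    report.config["seed"] = config.seed

    def finish_stage(stage: str, t0: float) -> None:
        report.stages[stage] = "ok"
        report.elapsed[stage] = round(time.perf_counter() - t0, 3)

    def fail(stage: str, exc: Exception) -> None:
        report.stages[stage] = "failed"
        (outdir / "report.json").write_text(report.to_json())
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    matrix: ExpressionMatrix
    labels: CohortLabels
    signature: GeneSignature | None = None

    # ---- inputs -----------------------------------------------------------
    stage = "simulate"
    t0 = time.perf_counter()
    try:
        if config.mode == "synthetic":
            _log("generating synthetic cohort")
            spec = SyntheticSpec(
                classes=list(config.classes),
                n_genes=config.n_genes,
                signature_size=config.signature_size,
                effect_matrix=block_effect_matrix(
                    len(config.classes), config.signature_size, config.delta
                ),
                noise_sd_range=(config.noise_lo, config.noise_hi),
                batch=(config.n_batches, config.batch_sd) if config.n_batches else None,
                batch_confounded=config.batch_confounded,
                seed=stage_seed(config.seed, "simulate"),
            )
            cohort = generate_cohort(spec)
            matrix, labels = cohort.matrix, cohort.labels
            signature = cohort.signature
            write_expression_matrix(matrix, outdir / "matrix.tsv")
            write_labels(labels, outdir / "labels.tsv")
            with open(outdir / "truth.tsv", "w") as fh:
                fh.write("gene_id\tclass\n")
                for gene, cls in sorted(cohort.truth):
                    fh.write(f"{gene}\t{cls}\n")
            manifest = {
                "seed": config.seed,
                "stage_seed": spec.seed,
                "classes": [list(c) for c in config.classes],
                "n_genes": config.n_genes,
                "signature_size": config.signature_size,
                "delta": config.delta,
                "noise_sd_range": [config.noise_lo, config.noise_hi],
                "batch": [config.n_batches, config.batch_sd] if config.n_batches else None,
            }
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            finish_stage(stage, t0)
        else:
            matrix = read_expression_matrix(config.expr)
            labels = read_labels(config.labels)
            if config.signature:
                signature = read_signature(config.signature)
            report.stages[stage] = "skipped"
    except RuntimeError:
        raise
    except Exception as exc:
        fail(stage, exc)

    restricted = subset_by_signature(matrix, signature) if signature is not None else matrix
    report.results["n_samples"] = matrix.n_samples
    report.results["n_genes_analyzed"] = restricted.n_genes

    # ---- cluster stability ------------------------------------------------
    stage = "stability"
    if config.run_stability:
        t0 = time.perf_counter()
        try:
            _log(f"cluster stability, k in [{config.k_min}, {config.k_max}]")
            res = ClusterStability(restricted).fit(
                k_range=(config.k_min, config.k_max),
                n_resamples=config.resamples,
                subsample_fraction=config.subsample_fraction,
                restarts=config.restarts,
                alpha=config.alpha,
                seed=stage_seed(config.seed, "stability"),
            )
            res.summary().to_csv(outdir / "stability.tsv", sep="\t", index=False)
            (outdir / "stability.json").write_text(
                json.dumps(
                    {
                        "k_selected": res.k_selected,
                        "p_per_k": {str(k): v for k, v in res.p_per_k.items()},
                        "alpha": config.alpha,
                        "n_resamples": config.resamples,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            report.results["k_selected"] = res.k_selected
            finish_stage(stage, t0)
        except Exception as exc:
            fail(stage, exc)
    else:
        report.stages[stage] = "skipped"

    # ---- learnability -----------------------------------------------------
    stage = "learnability"
    if config.run_learnability:
        t0 = time.perf_counter()
        try:
            _log(f"learnability test ({config.scheme})")
            test_labels = labels
            if config.merge_source and config.merge_target:
                test_labels = merge_classes(labels, config.merge_source, config.merge_target)
            fitted = LearnabilityTest(
                restricted,
                test_labels,
                scheme=config.scheme,
                roles=tuple(config.roles) if config.roles else None,
                n_swaps=config.n_swaps,
            ).fit(
                folds=config.folds,
                reps=config.reps,
                cap=config.cap,
                seed=stage_seed(config.seed, "learnability"),
            )
            r = fitted.result
            with open(outdir / "perturbed_accuracies.tsv", "w") as fh:
                fh.write("accuracy\n")
                for a in r.perturbed_accuracies:
                    fh.write(f"{repr(float(a))}\n")
            (outdir / "learnability.json").write_text(
                json.dumps(
                    {
                        "scheme": r.scheme,
                        "original_accuracy": r.original_accuracy,
                        "p_empirical": r.p_empirical,
                        "n_enumerated_total": r.n_enumerated_total,
                        "n_scored": len(r.perturbed_accuracies),
                        "exhaustive": r.exhaustive,
                        "folds": config.folds,
                        "reps": config.reps,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            report.results["original_accuracy"] = r.original_accuracy
            report.results["p_empirical"] = {r.scheme: r.p_empirical}
            finish_stage(stage, t0)
        except Exception as exc:
            fail(stage, exc)
    else:
        report.stages[stage] = "skipped"

    # ---- differential expression -----------------------------------------
    stage = "de"
    signature_genes: list[str] = []
    if config.run_de:
        t0 = time.perf_counter()
        try:
            contrasts = config.contrasts
            if contrasts is None:
                first = labels.classes[0]
                contrasts = [(first, other) for other in labels.classes[1:]]
            _log(f"differential expression, contrasts {contrasts}")
            de_res = DifferentialExpression(restricted, labels).fit(contrasts)
            for table in de_res.tables:
                name = f"de_{table.contrast[0]}_vs_{table.contrast[1]}.tsv"
                table.frame.to_csv(outdir / name, sep="\t")
            sig_frame = de_res.call_signature(
                config.lfc_threshold, config.fdr_threshold, config.rule
            )
            sig_frame.to_csv(outdir / "de_signature.tsv", sep="\t")
            signature_genes = list(sig_frame.index)
            report.results["n_signature_genes"] = len(signature_genes)
            report.results["lambda_star"] = {
                f"{t.contrast[0]}_vs_{t.contrast[1]}": t.lambda_star for t in de_res.tables
            }
            finish_stage(stage, t0)
        except Exception as exc:
            fail(stage, exc)
    else:
        report.stages[stage] = "skipped"

    # ---- enrichment -------------------------------------------------------
    stage = "enrich"
    if config.run_enrich:
        t0 = time.perf_counter()
        try:
            _log("category over-representation")
            categories = _read_categories(config.categories)
            table = fisher_enrichment(
                set(signature_genes),
                set(restricted.gene_ids),
                categories,
                fdr_threshold=config.fdr_threshold,
            )
            table.to_csv(outdir / "enrichment.tsv", sep="\t")
            report.results["enriched_categories"] = sorted(
                table.index[table["enriched"]].tolist()
            )
            finish_stage(stage, t0)
        except Exception as exc:
            fail(stage, exc)
    else:
        report.stages[stage] = "skipped"

    (outdir / "report.json").write_text(report.to_json())
    _log("run complete")
    return report
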