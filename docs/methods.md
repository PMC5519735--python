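# Methods

`lymphosig` asks whether a hypothesized sample class in a transcriptome
cohort — the motivating case is a putative lymphoma category placed next to
two established ones — behaves like a real, distinct biological group. It
answers with three independent lines of evidence, each implemented as a
model/results pair, plus a synthetic-cohort generator that provides
ground-truth data for all of them.

All analyses consume a log2-scale expression matrix (genes × samples,
post-normalization) restricted to a gene signature: an a-priori panel of
probes believed to be discriminative for the biology in question. The
restriction is part of the design, not a feature-selection step — the panel
is fixed before any labels are seen.

## Synthetic cohorts

The generator draws

    x_gs = mu_g + delta[class(s), g] * 1[g in signature] + b_batch(s) + eps_gs

with `mu_g ~ U(4, 12)` (the span of log2 microarray intensities),
`eps_gs ~ N(0, sigma_g^2)`, `sigma_g ~ U(noise_lo, noise_hi)` and optional
batch effects `b ~ N(0, batch_sd^2)` assigned either balanced within class
or confounded with class. Gaussian noise on the log2 scale matches the
distributional assumption behind the moderated t-statistic; per-gene
baselines make genes exchangeable but not identical. Named RNG sub-streams
(baselines, noise scales, batch, residuals) are derived from one seed, so
toggling the batch model does not shift the residual draws, and the same
`(spec, seed)` always reproduces the same cohort bit for bit.

Two planted-effect layouts are provided. `blocks` gives each class its own
contiguous block of signature genes shifted by `delta` — distinct marker
sets per class, the natural model for cluster-recovery experiments.
`rotation` assigns the levels `0, delta, 2*delta, ...` to the classes in a
rotating pattern across signature genes, so every class pair differs by at
least `delta` on every signature gene — the natural model for "the classes
differ by delta on the panel" classification experiments. Planted cohorts
default to a signature covering 30 % of genes, mirroring panels where a
minority of probes carries the class contrast.

What the generator does **not** emulate: probe-level cross-hybridization,
intensity-dependent variance, spatial array artifacts, correlated gene
modules beyond the planted effects, or count data. Passing tests therefore
demonstrate correctness of the statistical machinery under its stated
model, not robustness to every failure mode of real arrays.

## Cluster stability and the number of clusters (`ClusterStability`)

For each candidate `k`, the procedure draws two subsamples of
`ceil(f * S)` samples (default `f = 0.8`), clusters each with seeded
k-means (squared-Euclidean inertia, k-means++ initialization, 10 restarts,
ties broken by first occurrence), and scores their agreement on the shared
samples with the **MCA index**: the fraction of samples co-assigned under
the best injective matching of cluster labels, computed exactly by
maximum-weight bipartite matching on the contingency table (padded square
when the two partitions have different `k`). `B = 50` replicates per `k`
form the data distribution.

The baseline ("random clustering") arm runs the *identical* protocol on
structure-destroyed data: reference matrices in which each gene's values
are independently permuted across samples. This choice is load-bearing.
Because the two subsamples share samples, k-means agreement exceeds that of
independent random partitions even on pure noise; a baseline of uniform
random partitions is therefore systematically beaten at every `k` on any
input, and a replicate-level rank-sum test against it declares every `k`
"significant" even on structureless cohorts (we measured p between 1e-6
and 1e-20 at all k on pure-noise data). Only a baseline that preserves the
subsample coupling — clustering permuted matrices with the same machinery —
is calibrated.

Significance is assessed at the matrix level. The per-`k` statistic is the
mean MCA; it is computed for the data matrix (over `B` replicates) and for
`R = 24` gene-wise permuted reference matrices (`B' = 5` replicates each).
Per-`k` z-scores against the reference moments are combined through the
maximum across the candidate range, giving family-wise adjusted permutation
p-values: under the no-structure null the data matrix is exchangeable with
its gene-wise permutations, so the probability that *any* `k` appears
significant on a structureless cohort is at most `1/(R+1) ≈ 4 %` — exactly,
regardless of the correlation between replicates that invalidates
replicate-level tests. (The data statistic averages more replicates than
the references, which makes the test slightly conservative, never
anti-conservative.) `R` must satisfy `1/(R+1) < alpha`.

The selected number of clusters is, among the significant `k`, the one
with **maximal median data MCA**, ties resolved toward larger `k` — the
most stable demonstrably non-random cluster solution. The rationale: when
well-separated groups exist, forcing a finer `k` sub-splits tight clusters;
such sub-splits retain substantial (and genuinely non-random) agreement
from the intact clusters, so "the largest significant k" saturates at the
top of the candidate range, while maximal stability identifies the planted
structure. The literal largest-significant-k reading remains available as
`select_k(profile, rule="highest_significant")`.

Agglomerative clustering (`hierarchical_partition`) supports euclidean and
1−Pearson distances with average, complete, or Ward linkage; defaults are
euclidean + average. A zero-variance sample under the correlation distance
is an error naming the sample.

## Class learnability (`LearnabilityTest`)

The test asks whether a labeling supports higher cross-validated accuracy
than labelings obtained by exchanging samples between the putative class
and the reference classes.

*Classifier.* Soft-margin linear SVM on every gene of the supplied
(signature-restricted) matrix — no feature selection — with `C = 1`,
gene-wise standardization whose parameters are fit on the training folds
only, and one-vs-one multiclass reduction (libsvm voting; vote ties resolve
to the lowest class index, i.e. class order). `C` is deliberately fixed,
not tuned: accuracy on standardized expression panels is insensitive to it
over 0.01–10 (measured), and tuning would leak information into the
permutation comparison.

*Protocol.* Repeated stratified k-fold CV (default 10×10; the power studies
use 5×5). Accuracy is pooled over held-out folds within a repetition
(integer correct counts, so comparisons between labelings are exact) and
averaged over repetitions. Per-repetition fold seeds derive
deterministically from the test seed.

*Perturbations.* `three_class_exchange` swaps two putative-class samples
against one sample of each reference class (`m1↔a`, `m2↔g`), giving
`n_M(n_M−1)·n_A·n_G` distinct labelings; `pair_exchange(m)` swaps `m`
cross-class pairs in a two-class labeling (`C(n_A,m)·C(n_B,m)` labelings).
Enumeration is exhaustive up to `cap` (default 10 000); beyond it, a seeded
uniform sample without replacement of `cap` distinct labelings is drawn by
unranking indices (mixed-radix for the double swap, combinatorial number
system for subset swaps) — exactly uniform, no rejection loop. The
two-class experiment is realized as `merge_classes` followed by
`pair_exchange` against the merged labeling.

*Inference.* Every labeling is scored with the identical protocol and seed
rule; the empirical p-value uses the add-one permutation form
`p = (1 + #{perturbed ≥ original}) / (1 + N)`, which can never report 0 and
differs from the plain fraction by O(1/N).

## Differential expression (`DifferentialExpression`)

The shrinkage t moderates per-gene variances toward the across-gene median
pooled variance with an analytically estimated intensity (formulas in
`lymphosig/de.py`): `lambda* = min(1, sum_g Var(v_g) / sum_g (v_g −
v_median)^2)`, set to 1 when the denominator vanishes (then every statistic
reduces exactly to the ordinary pooled t computed with the common
variance). Two-sided p-values come from the Student-t reference with
`n − 2` df; for very small groups a seeded gene-wise permutation p-value is
available. The signed log2 fold change is `mean(first-named group) −
mean(second-named group)`; every table records its contrast, because "A vs
B" column headers are otherwise ambiguous.

A gene enters the signature for a contrast if `|delta| > 1` and BH-FDR
`q < 0.05` (defaults). Across contrasts the default combination rule is the
**union**: with two reference classes, a biologically coherent marker may
clear the fold-change cut against one reference only, and discarding it
would understate the signature. The intersection rule is available.

Category over-representation uses the one-sided Fisher exact test — the
hypergeometric upper tail of the 2×2 in/out-signature × in/out-category
table over the analysis universe — with BH adjustment across categories.
Categories are a user-supplied flat mapping; no ontology traversal or term
propagation is performed.

## Pipeline (`run_full_analysis`)

Stages run in order (simulate → signature restriction → stability →
learnability → DE → enrichment) on the signature-restricted matrix, each
consuming only prior artifacts and the config. One global seed governs a
run; per-stage seeds are the first four bytes of `sha256("<seed>:<stage>")`,
so disabling one stage never shifts another's stream. The effective config
is echoed into the output directory; results live only in files, never only
in logs; two runs with the same config and seed produce bit-identical
numerical artifacts (the report's wall-clock timings are the one exception).
Config files are flat `key = value` text; CLI flags override file values.

## Numerical and testing choices

- Expression TSVs are written with `repr` floats (17 significant digits) so
  write → read round-trips bit-identically.
- MCA uses `scipy.optimize.linear_sum_assignment`; its exactness is tested
  against exhaustive bijection search on hundreds of random partition pairs.
- BH-FDR is a five-line vectorized step-up, cross-checked in tests against
  both a quadratic-time transcription of the definition and statsmodels.
- The shrinkage-t implementation is verified against an independent
  plain-loop oracle to 1e-12 and against its two analytic limits.
- Subsample replicates whose intersection is smaller than `k` are redrawn
  (error after 100·B redraws, advising a larger subsample fraction).
- Tests use problem sizes chosen for tight statistical margins at desk
  scale: 100-gene panels, 8–12 samples per class, B = 50 stability
  replicates, 200 sampled relabelings, 40–100 seeds per calibration or
  power estimate.

## Known limitations

- The stability baseline destroys *all* structure; it cannot distinguish
  "classes" from strong non-class structure (e.g. a severe batch effect
  will legitimately register as structure). The generator's confounded
  batch mode exists precisely to study this.
- The learnability p-value is conditional on the exchange scheme; schemes
  touching more samples probe coarser alternatives.
- The shrinkage-t assumes approximately Gaussian per-gene residuals on the
  log2 scale and a common variance target; heavy-tailed contamination is
  better served by the permutation p option.
- With `cap` below the enumeration total, the reported p carries Monte
  Carlo error of order `1/sqrt(cap)`.
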