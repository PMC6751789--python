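# Methods

## Model

A feature-by-sample expression matrix *E* (n × m, log-like scale) is
modelled as a noisy linear mixture of k statistically independent,
non-Gaussian source signals:

    E ≈ S · M + per-feature offsets

The per-feature offsets are the row means removed before decomposition and
restored on reconstruction.  Identifiability rests on the classic ICA
assumptions: sources mutually independent, at most one Gaussian, mixing of
full rank.  Transcriptional programmes fit this well — a metagene typically
has a heavy-tailed loading distribution (few marker genes, many near-zero
loadings) — whereas purely Gaussian structure (e.g. white technical noise)
is only recoverable as a single component.

### Consensus procedure

1. `nt` FastICA runs (scikit-learn: logcosh contrast, parallel extraction,
   SVD whitening, tol 1e-6, max 1000 iterations; all configurable), each on
   the matrix with one uniformly drawn sample removed (drawn with
   replacement across runs).
2. Run 1 is the "standard" (configurable to the run most correlated with
   all others); every run is aligned to it by greedy metagene-correlation
   matching (descending |r|, ties to the lower index), which resolves
   ICA's permutation and sign ambiguity.
3. The consensus *S* is the mean of the aligned run metagenes, columns
   rescaled to unit standard deviation (FastICA fixes source variance only
   up to convention; one convention makes top-contributor thresholds and
   stabilities comparable).  The consensus *M* is the least-squares
   projection of the centred data onto the consensus *S*, so *S·M* is an
   actual least-squares reconstruction; run-level weight matrices are
   likewise completed for all m samples by projection, since each run
   lacks one sample.
4. Stability R² per component is the mean squared Pearson correlation of
   the component's metagene between every pair of aligned runs, computed
   via a Gram matrix (O(nt²·n) per component).  The pairwise form was
   chosen over correlation-with-the-consensus because the latter
   self-inflates (every run is part of the average it is compared with)
   and visibly under-reports instability of surplus components.
5. Metagenes are read out as uncentred projections of the data onto the
   unmixing directions.  This differs from FastICA's internal scores by a
   scalar shift per component (irrelevant to correlations and robust
   z-scores) but keeps every metagene inside the data column space, so
   noiseless rank-k data reconstructs exactly.

Determinism: per-run seeds and excluded samples are derived up front from
one seed via `numpy.random.SeedSequence` sub-streams; parallel execution
(joblib) returns runs in submission order, so results are bitwise
independent of the worker count.

Convergence: symmetric FastICA does not converge when k exceeds the
effective signal rank and the algorithm must extract noise-bulk
directions — it oscillates until max_iter at any tolerance.  Since
over-decomposition is exactly the regime the stability index is meant to
diagnose, non-converged runs are kept by default and only counted in the
provenance (`n_converged`); `discard_nonconverged=True` switches to
discarding them and erroring when more than half fail.

## Downstream machinery

**Top contributors.**  Within a metagene, z = (s − median)/(1.4826·MAD)
(MAD scaled for normal consistency), two-sided normal p-values, BH
adjustment across the component's features, adj.p < 0.01 by default,
split by z sign.  The robust centre/scale stops the markers themselves
from inflating the background variance.  A constant metagene (MAD 0) is an
error, not an empty result.

**Orientation.**  With gene sets: a component flips when the best
enrichment p among its negative-side contributors beats the positive side.
Without: the heavier significant tail goes positive.  miRNA components,
which lack informative set annotation, flip only when their
best-correlated mRNA component shows r < −0.5 ("strong negative" is not
canonically quantified; 0.5 mirrors the linking threshold |r| > 0.5).
All orientation operations are idempotent and preserve S·M exactly.

**Survival.**  One univariable Cox fit per component on the row-standardised
weights (lifelines), so LHRs are per standard deviation and comparable.
Significance comes from the hand-written score test at β = 0 with Breslow
tie handling — for a single covariate this is the log-rank trend test that
R's `summary(coxph)$sctest` reports (verified against it) — BH-adjusted
across the k components.  The risk score RS = Σ Hᵢ·R²ᵢ·M*ᵢ uses Hᵢ = LHR
when adj.p < 0.05 else 0; the standardisation mean/sd are frozen from the
discovery cohort so that validation scoring involves no leakage.  RS is
invariant to ICA's sign convention and identically 0 when nothing passes.

**Classification / k selection.**  Random forest (scikit-learn defaults,
seeded) on weight columns with leave-one-out cross-validation; nested
selection of k holds out 20%, decomposes the remainder at each candidate
k (nt = 5 by default — model selection needs only relative accuracy),
projects the held-out samples onto the training metagenes, and applies the
one-standard-error rule over outer repeats, preferring the smallest
adequate k.

**Linking.**  Components (within or across omics layers) are joined when
the squared Pearson correlation of their weight rows over the shared
samples strictly exceeds r² = 0.25; clusters are connected components of
that graph (no finer community detection — the evidence is a thresholded
correlation, nothing more).

**Ranking score.**  Fraction of discovery weights strictly below the new
weight, ties counted half (mid-rank), clamped to exactly 0/1 outside the
discovery range.  Invariant under any strictly increasing transform
applied jointly to discovery and new weights.

## Preprocessing

Soft count filtering uses a strictly-greater comparison (a feature passes
with value > threshold in ≥ min_samples samples); log2 uses a pseudocount
of 1 by default.  qPCR Ct tables are inverted as limit − Ct with missing
values and Ct above the limit (36 by default) set to the limit, i.e.
expression 0 at the detection boundary.  Microarray-to-RNA-seq
harmonisation fits a single affine map on the pooled value distributions —
median/MAD matching by default (robust to expression's heavy tails), with
a quantile-regression alternative — and is exact for inputs already affine
in the reference.  Cohort concatenation intersects feature ids by exact
string identity and refuses duplicate sample ids.

## Synthetic data: what it does and does not emulate

The generator produces E = S·M + noise (+ batch offsets) with Laplace
sources (scale 1 — the simplest super-Gaussian satisfying ICA
identifiability) or sparse-spike sources mimicking marker-driven
metagenes; mixing weights N(0,1); i.i.d. Gaussian noise.  The reference
benchmark is 5 sources, n = 2000, m = 100, noise sd 0.1; the "noisy"
variant used for reproducibility comparisons raises the noise sd to 1.0,
where single runs visibly scatter.  Batch structure is an additive
per-feature offset on a trailing sample block, drawn Laplace: an additive
shift is the simplest mechanism consistent with cohorts separating along
one direction in PCA space, and a Laplace offset profile keeps the batch
direction itself ICA-recoverable (a Gaussian profile would be the one
source family the model cannot isolate).  Survival times are exponential
with hazard baseline·exp(β·w*) and independent uniform censoring whose
horizon is calibrated by bisection to the requested censoring fraction.

Real data differ in ways the generator deliberately ignores: sources are
only approximately independent, noise is feature-dependent and partly
multiplicative, batch effects are not purely additive, hazards are not
exponential, and feature counts are 10–30× larger.  Passing tests
therefore demonstrate correctness of the machinery under the model's own
assumptions, not performance guarantees on clinical cohorts.

## Numerical choices and degeneracies

- Problem sizes in the test-suite and acceptance benchmarks (n ≈ 400–5000,
  m ≈ 40–300, nt ≈ 2–50, 3–100 replicates per property) are chosen so each
  property is measured well inside sampling error while the full suite
  stays desk-scale.
- Greedy component matching breaks correlation ties toward lower indices;
  exhaustive matching is used as the oracle in tests for k ≤ 4.
- Least-squares weight projection raises on rank-deficient metagene
  matrices rather than regularising.
- Degenerate inputs fail loudly: empty filter results, constant metagenes,
  all-censored cohorts, single-class labels, < 3 shared samples/features.
- Harrell-type concordance between risk scores and the generating linear
  predictor is computed as the concordant-pair fraction, (Kendall τ + 1)/2.

## Known limitations

- k is not estimated automatically from information criteria; choose it
  via `select_num_components` or domain knowledge.
- No multivariable or penalised Cox models, no competing risks.
- No probe-to-gene mapping, normalisation (DESeq2/FPKM/TPM) or gene-symbol
  aliasing; matrices are taken as given, intersected by exact id.
- Within-layer linking reuses the cross-layer operation; no community
  detection beyond connected components.
- Plot generation is intentionally absent from the deterministic pipeline
  outputs.
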