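# Methods

## Data model and conventions

All computation is on samples × probes matrices.  Counts enter as
non-negative integers (RCC `Code_Summary` rows or a counts CSV) and become
real-valued after scaling; expression is always log2.  The log transform is
`log2(max(count, floor) + offset)` with offset 1 by default; at offset 0 the
floor is 1 so zero counts map to 0 rather than −∞.  Base 2 keeps fold
changes readable; the +1 offset guards against the zeros that background
subtraction creates.

Probe classes are normalized case-insensitively from the RCC dialects:
`Housekeeping`/`Control`/`HK` → Housekeeping, `Negative` → Negative,
`Positive` → Positive, everything else (including `Endogenous1`-style
variants) → Endogenous.  Lane assembly checks probe order strictly by
default; reordering by name is an explicit opt-in, because silent reordering
is a classic corruption source.

## RUV-III

Given the replicate design M (each assay → its biological sample,
m′ distinct samples), the fit:

1. centre each gene; store the means for restoration, so no unwanted
   dimension is spent on the grand mean;
2. R = Y₀ − M(MᵀM)⁻¹MᵀY₀ (group-mean projection, applied without forming
   the m × m projector);
3. SVD of R (not the eigendecomposition of RRᵀ — same subspace, better
   conditioning); keep the first k_max = min(m − m′, #controls) left
   singular vectors U, with a deterministic sign convention
   (largest-magnitude coordinate positive) so serialized fits reproduce;
4. fullalpha = UᵀY₀, α = its first k rows, and
   W = Y₀[:, ctl] α_cᵀ (α_c α_cᵀ)⁻¹ over the control genes.  A numerically
   singular Gram matrix (condition number > 1e12) falls back to the
   Moore–Penrose pseudo-inverse with a warning rather than failing: small
   control sets with k near k_max are common.

Only the product W α is identified (any invertible k × k transform of the
pair gives the same fit), so tests assert W α, or correlation magnitudes of
single factors, never W entrywise.

k = 0 is the identity.  `average=True` collapses each replicate group to its
mean, (MᵀM)⁻¹MᵀŶ.  There is no automatic k selection: the intended workflow
is to refit over a range of k and judge the diagnostics.

Leave-pair-out TRA refits with one pair split into singletons.  If dropping
the pair lowers k_max below the requested k, the refit caps k at the new
k_max (logged) instead of erroring, so the leave-out series stays
comparable at k = k_max.

## Conventional nCounter grid

Stage order is positive-control scaling → background subtraction →
sample-content scaling, following the NanoStringNorm convention.  All
factors use the arithmetic mean of the per-sample statistics as the common
target.  Background (none / mean / mean+2·sd / max of the NEG spike-ins,
unbiased sd) is subtracted from every non-Negative probe and floored at 0;
it is not applied to Positive probes, which no later stage uses — the
alternative (correcting them too) only changes a stage that is never read.
Content modes: HK sum, HK geometric mean, total endogenous sum, mean or
geometric mean of the top-75 genes by grand mean, and geometric mean of the
lowest-CV decile (top_n and the quantile are configurable).  HK genes are
background-corrected before content normalization like any other
non-Negative probe.  3 × 4 × 7 = 84 combinations; `grid_evaluate` scores
each with the RLE-median spread, the pooled TRA IQR and optionally a named
gene-pair correlation.

## Differential expression

Two-group comparisons only — each contrast in the intended workflow is
pairwise, so a full design-matrix stack is unnecessary.  Per gene: logFC is
the difference of group means, s² the pooled variance with df = m − 2.
Moderation follows the standard empirical-Bayes derivation: a scaled
inverse-χ² prior (d0, s0²) is moment-matched on log s² (digamma/trigamma
relations, trigamma inverted by Newton), the posterior variance is
(d0·s0² + df·s²)/(d0 + df) and the moderated t has df + d0 degrees of
freedom.  Genes with zero residual variance are excluded from the prior fit
with a warning.  d0 = 0 reproduces the ordinary t exactly; d0 = ∞ gives
every gene the prior variance and a normal reference.  The implementation
is checked against limma's `lmFit`/`eBayes` (agreement ~1e−10 on a
fixture).  P-values are unadjusted by default; Benjamini–Hochberg is
available behind a flag.  Volcano y is −log10 p (p floored at 1e−300), with
a `10log10` scale flag.

## Synthetic experiments

The generator draws log2 signal = 1μᵀ + Xβ + Wα + lib + ε and sets counts =
round(2^signal), keeping the log-scale truth exact; a count-distribution
model (e.g. negative binomial) would blur the planted structure without
exercising any additional code path, since all methods operate on log
counts.  Unwanted factors are batch-level scores (shared by every assay in
a cartridge/CodeSet/era) times gene loadings — exactly the rank-k model
class RUV-III assumes.  The per-assay library factor models sample content
and applies to endogenous, HK and POS probes.  POS spike-ins follow a fixed
6-step geometric ladder (log2 counts 15 down to 5, ~3 orders of magnitude,
platform convention); NEG spike-ins are Poisson around a flat background
(mean 10) untouched by biology, batch and library factor — spike-ins only
see unwanted variation from the point at which they are added.  Technical
replicates are fresh assays of the same biological sample: new noise, new
library factor, and the unwanted score of whatever batch the replicate
lands in (`within_batch`, `spanning`, or `confounded` placement).

Defaults describe a well-designed mid-size study: 54 biological samples in
3 batches, 480 endogenous + 6 HK probes plus the 8 NEG / 6 POS spike-ins
(500 probes), one unwanted factor with batch-score sd 1.5 (log2), noise sd
0.3, library-factor sd 0.2, and 10% technical replicates spanning batches —
the recommended floor of at least one replicate per cartridge.

What the generator does **not** emulate: per-probe capture efficiencies,
count-level overdispersion, probe-specific backgrounds, or real panel
compositions.  Passing tests therefore demonstrate correctness of the
algorithms under the model they assume, not performance on any particular
real dataset.

### Presets

* `codeset_batches` — the defaults above; used for parameter-recovery and
  TRA-improvement checks.
* `late_bad_cartridge` — 5 batches, all-positive loadings and a −2 score
  for the last batch: its HK means and log totals dip while NEG/POS series
  stay flat, the signature of a content problem localized to one cartridge.
* `two_era_time_shift` — two eras with a −1.5 shift in the later one.
* `disconnected_batches` — two batches whose replicates all lie within a
  batch, with a large fixed between-batch shift (scores 0 and −4, small
  jitter).  This preset is deliberately a *small* pilot (8 biological
  samples): with a single bridging pseudo-replicate pair the loading
  estimate carries per-gene error of order √2·noise_sd independently of
  the batch magnitude, so the residual shift is detectable whenever
  per-batch n is large — one pair can rescue a small study, while larger
  disconnected studies need several bridging pairs.  Batch-effect
  magnitudes in all presets are arbitrary, chosen so the raw-data
  diagnostics visibly show each failure mode.

## Numerical choices and edge cases

* Variance for lowest-variance control selection: unbiased sample variance
  of log2 expression, ties broken by column order; an external reference
  matrix sharing probe names may supply the variances.
* Geometric means floor their inputs at 1 (the log rule at offset 0) so a
  zero count cannot annihilate a scaling statistic.
* RLE box summaries use the Tukey 1.5·IQR whisker convention.
* TRA: replicate groups of size g contribute all g(g−1)/2 pairs; member
  order is run order, making ratio signs deterministic.
* PCA: gene-mean-centred SVD; the correlation-matrix variant standardizes
  genes and drops zero-variance genes with a warning; deterministic sign
  convention as in the RUV-III fit.
* Problem sizes in tests and the acceptance script (≤ 60 assays, ≤ 500
  probes, 50 small oracle instances) are chosen to exercise every code path
  while keeping the full suite in seconds.

## Known limitations

* No RUV-2/RUV-4/RUVg (replicate-free) variants, and no RUV-I/eta
  pre-adjustment.
* No automatic choice of k or of pseudo-replicate pairs; the package
  applies declared pairs and reports batch connectivity, it does not match
  samples.
* Only the gene-expression RCC dialect is parsed (no miRNA/CNV/protein
  variants) and no binding-density QC flags are computed.
* The DE module handles a single two-level factor; multi-level designs must
  be expressed as pairwise contrasts.
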