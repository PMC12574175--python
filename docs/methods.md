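# Methods

## Problem and model

`cernet` infers a competing-endogenous-RNA (ceRNA) co-regulation network
from two-condition expression profiling of a luminal-B breast-cancer
model. The biological reasoning it encodes:

1. A miRNA represses its mRNA targets, so a genuine regulatory pair in a
   contrast (3D spheroid vs 2D monolayer culture) should show *inverse*
   differential expression: miRNA down with target mRNA up (or the
   reverse), and the pair must be supported by interaction-database
   evidence (predicted, curated, or CLIP).
2. A miRNA whose change replicates with the same sign in an independent
   tumor-vs-cell-line cohort (matched by standard miRNA name, never by
   probe re-annotation) is a *direction-concordant* candidate with
   putative in vivo relevance.
3. Up-regulated lncRNAs can sponge down-regulated miRNAs, de-repressing
   the miRNAs' up-regulated targets. The assembled network is therefore
   tripartite — sponge edges lncRNA→miRNA and regulation edges
   miRNA→mRNA — and a miRNA enters it only with at least one edge of
   each kind. Hubs are ranked by unweighted total degree (regulation +
   sponge), ties broken by identifier.
4. Hub miRNAs are scored as single-feature diagnostic biomarkers by the
   tie-aware rank-sum AUC (probability a random positive-class value
   exceeds a random negative-class value, ties counted half), with the
   orientation-corrected `reported_auc = max(AUC, 1 − AUC)` emitted
   alongside the raw value.

## Statistical machinery

**Moderated t (cell-culture contrasts).** For the small-n 3D-vs-2D
contrasts each feature's pooled two-group residual variance s²_g
(d_g = n−2 df) is shrunk toward a prior s₀² by empirical Bayes:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
    t_g  = (x̄_alt − x̄_ref) / (s̃_g · √(1/n_ref + 1/n_alt)),   df = d₀ + d_g.

(d₀, s₀²) come from the closed-form method of moments on log variances:
under s²_g ~ s₀²·F(d_g, d₀), e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has
variance ψ′(d_g/2) + ψ′(d₀/2), so d₀ is a trigamma inversion (Newton
iteration) of the excess spread of e_g and s₀² the corrected mean. When
the observed spread does not exceed the χ² expectation, d₀ = ∞ and every
feature is fully shrunk to s₀² = exp(mean e) — note this bias-corrected
value differs from the raw common s² by the factor exp(log(d/2) −
ψ(d/2)) (≈1.31 at d=4); it is what the estimator, and Bioconductor's
limma, return. The unit suite pins the whole fit against frozen
limma 3.58.1 `lmFit`+`eBayes` output on a committed 200×6 matrix at
≤1e-6 relative (observed ~1e-12).

**Welch t (tumor contrast).** The tumor-vs-cell-line cohort uses
per-feature two-sided Welch tests — unequal variances and sentinel
missingness make pooled or moderated variance inappropriate across
platforms. No moderation is borrowed across cohorts, and
Benjamini–Hochberg FDR is applied per contrast, never pooled.

**Thresholds.** Default classification: linear FC > 1.5 (strict) and
BH q < 0.05, with `use_q=False` exposing a raw-p preset and `fc_min`,
`alpha` configurable. Linear fold change is 2^log2FC; a signed display
convention is reporting-only.

**Detection and sentinels.** Agilent-style exports mark "not detected"
with the sentinel −9.969; sentinel cells are masked at read time (value
retained for audit) and excluded from every mean, variance, and test.
The default detection filter keeps a feature only if every cell is
unmasked and > 1 on the log2 scale (the strictest reading of an
"RMA > 1 across samples" rule: a not-detected cell cannot certify
detection); a per-group-mean scope is available as configuration, and
the filter is applied per cohort.

**Enrichment.** Over-representation is the hypergeometric upper tail
P[X ≥ overlap] over user-supplied GMT collections, BH-adjusted across
the collection; the default universe is the features surviving the
detection filter in the relevant matrix (the least biased choice when
nothing else is stated).

## Degenerate inputs

Zero-variance features are a first-class case because the σ=0 contract
of the generator (below) requires exact truth recovery:

* Welch with both sides constant and equal means → "degenerate
  variance"; the feature is reported with NA statistics and logged,
  and classified not-significant.
* Both sides constant with unequal means → perfect separation,
  t = ±∞, p = 0.
* One side constant → Welch formulas evaluated directly (the
  textbook expressions are well defined; df collapses toward the
  varying side).
* Moderated fit with no positive residual variance → d₀ = ∞ tag with
  s₀² = 0; zero posterior variance then maps to t = ±∞/0 and p = 0/1
  by the sign of the mean difference.

Constant samples are detected by exact value identity, not by comparing
a computed variance to zero (mean subtraction leaves ~1e-30 residues on
identical floats).

## Synthetic data: what it emulates and what it does not

The generator (`cernet.simulate`) produces the full study layout from
one seed: a 3D-vs-2D miRNA cohort, a matching mRNA cohort, an
independent tumor-vs-2D miRNA cohort on its own "platform" (separate
baselines, partially overlapping feature names), interaction tables
with planted true pairs plus decoys, and a small gene-set collection.
All randomness flows through named `SeedSequence` substreams, so equal
seeds give bit-identical bundles.

Model: log2 intensity = per-feature baseline (uniform on [6, 12]) +
planted group effect + i.i.d. Gaussian noise. Gaussian noise on the
log2 scale matches microarray convention and keeps closed-form power
and AUC checks available (a 2σ shift gives AUC = Φ(2/√2) ≈ 0.921).

Reference conditions (`default_paper_scenario`): triplicates per
condition; four hub miRNAs down-regulated in both contexts with
disjoint target sets of 15+15+14+14 = 58 mRNAs and 3 sponges each
(12 lncRNAs); two further concordant-down miRNAs deliberately without
sponges (they must drop out of the network); eight concordant-up
miRNAs; five single-context DE miRNAs per direction per cohort as
concordance decoys; 300 miRNAs / 500 mRNAs / 30 lncRNAs total. Hub
effect sizes are drawn from the published concordance panel's log2FC
ranges ([−3.49, −1.11] in the 3D contrast, [−4.58, −1.97] in tumors);
up-concordant effects from the panel's up ranges. Default noise
σ = 0.3, a realistic replicate SD for normalized arrays.

Sentinel dropouts (default 2% of cells) are applied only to *null*
tumor-cohort features: the default detection filter drops any feature
carrying a sentinel, so sentinels on planted features would silently
break the σ=0 ground-truth contract; biologically, not-detected cells
belong to low-abundance features, which the planted signals are not.

Deliberate omissions: no probe-level effects, spatial artifacts, batch
structure, correlated noise, or expression-dependent variance. Passing
tests on this generator therefore demonstrate the *logic* of the
pipeline (directional filtering, concordance, assembly, ranking) and
the calibration of its statistics under idealized noise — not
robustness to real-array artifacts.

A consequence worth knowing: at σ = 0.3 the n=3 tumor contrast is
genuinely underpowered under per-feature Welch testing (no variance
moderation), so a realistic-noise run recovers only part of the planted
concordance set, and the assembled network is smaller than the planted
12/4/58 shape; the σ=0 bundle recovers it exactly. This mirrors the
real power ceiling of triplicate designs rather than a defect of the
implementation.

## Normalization choice

Quantile normalization (mean-reference-quantile flavor, ties receiving
the mean of their reference quantiles) is implemented and tested but is
*not* applied by default: the pipeline's inputs are authors'-normalized
log2 matrices analyzed per cohort on their native scales with no
cross-platform merging, and the generator emits normalized-scale data.
Applying it to already-normalized two-condition matrices would shrink
genuine group differences (at σ=0 it exactly halves planted effects in
the worst layout). It is available as `apply_quantile_normalization`
for raw matrices.

## Numerical and design choices

* Hierarchical clustering for heatmap ordering: Euclidean metric,
  average linkage, scipy's deterministic leaf order; permuting input
  rows permutes labels but not the merge heights.
* Name matching: case-sensitive, surrounding whitespace trimmed, no
  −5p/−3p arm inference, no probe collapsing; duplicate
  post-normalization names are a strict error (first-wins opt-in).
  miRNA arm variants (e.g. -539-3p vs -539-5p) are distinct names and
  are never reconciled.
* Interaction evidence from multiple sources is unioned per pair, not
  intersected.
* The lncRNA layer carries direction as annotation only (the ceRNA
  hypothesis expects sponges up-regulated, but the sponge evidence is
  prediction-level); a DE filter on lncRNAs is an opt-in, not a
  default.
* Network mRNA layer is the union over included miRNAs' targets
  ("any", not "all").
* Determinism: every output TSV uses fixed float formatting, JSON is
  key-sorted, and the run manifest records a seed, a config hash
  (excluding the output directory) and per-file SHA-256, so identical
  config+seed reproduce all outputs byte-identically.
* Problem sizes in the test and acceptance runs (300–500 features,
  triplicates, 20-seed calibration loops) are chosen as the smallest
  sizes at which the planted structure and the calibration bands are
  meaningful.

## Known limitations

* The moderated fit covers exactly two-group designs; no multi-factor
  models, no eBayes trend/robust variants, no batch correction.
* Welch on n=3 has low power; the package reports NA rather than
  guessing when preconditions fail.
* AUC confidence intervals (DeLong) are not emitted by default; no
  multivariate signatures or cross-validation.
* The published full-cohort counts (75/82 and 43/186 DE miRNAs,
  1,175/872 integrated mRNAs) depend on external accessions and
  database snapshots; they are carried in `cernet.reference` as
  provenance anchors and are not reproducible from bundled inputs.
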