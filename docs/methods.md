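# Methods

This note documents the models, defaults, and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Data model and conventions

Methylation is carried as probes × samples pandas DataFrames on two scales:
β ∈ [0,1] (interpretable methylation fraction) and M = log₂(β/(1−β))
(closer to homoskedastic; all linear modelling happens here). The logit is
clipped at ε = 1e−6 so β ∈ {0,1} stays finite; the inverse transform
round-trips to < 1e−9 inside (ε, 1−ε). Probe annotation carries chromosome,
1-based position, ≤1 gene per synthetic probe (';'-separated multi-gene
strings are legal in real manifests and contribute to every named gene),
a gene region in {TSS200, TSS1500, 5'UTR, Body, 3'UTR, intergenic}, and an
island relation in {Island, N/S_Shore, N/S_Shelf, OpenSea}. "Promoter"
always means TSS200 ∪ TSS1500.

BED intervals are 0-based half-open. A probe at 1-based position `pos` is
inside [start, end) exactly when `start < pos + 1 <= end`; chromosome names
are normalised so "chr1" ≡ "1". This rule is deliberately bit-exact: a probe
sitting at the open end of an interval is retained.

## Probe filtering

Filter reasons apply in a fixed order — detection → SNP → XY →
cross-hybridizing — and a probe removed by several lists is counted once,
under the first. The detection rule drops a probe whose failure fraction
across samples exceeds `max_fail_fraction` (default 0, i.e. one failing
sample suffices — the conservative reading of "failing probes were
removed"); the threshold is exposed for laxer policies. Mask IDs absent
from the matrix are ignored but counted. The cross-hybridizing list is user
input, never embedded.

## Batch adjustment

Parametric empirical-Bayes location/scale adjustment on M-values: per probe
the data are standardised against a design of batch indicators plus any
covariates to protect; per-batch locations γ and scales δ² are estimated and
shrunk toward batch-level priors (normal for γ, inverse-gamma for δ² with
method-of-moments hyperparameters, solved by the usual iterative conditional
updates to 1e−6); batch effects are then removed and the grand
location/scale and protected covariate effects restored. One deliberate
convention: within-batch variances are population (ddof=0) estimates,
consistent with the /n pooled variance, which makes the adjustment an exact
fixed point once batch effects are gone (a second application is a no-op on
zero-prior-variance fixtures). The widely used R implementation takes
sample (ddof=1) variances instead; agreement is therefore close (within a
few percent of data spread on random fixtures, verified in the test suite)
but not bitwise. The non-parametric variant is out of scope. A single batch
is an identity; batches with fewer than two samples are rejected.

## Source-of-variation screen and adjustment

Per probe, one joint linear model contains every declared factor
(categoricals one-hot with first-level reference, continuous factors
standardised). Each factor's marginal (type-III) F compares the full model
against the model with that factor's columns dropped; F is averaged across
probes. A joint model was chosen over per-factor one-way ANOVAs so that
correlated factors share variance honestly. The error reference is 1: a
pure-noise factor's mean F converges to ~1, and factors with mean F > 1 are
flagged as confounders. The group label is reported but never auto-selected.

Adjustment regresses M on intercept + confounders only (group deliberately
excluded, matching a residuals-then-test design) and keeps residuals with
the grand mean restored. When a confounder correlates with group this can
absorb part of the group effect — a known bias risk of the residual design;
the package reports diagnostics and never auto-corrects. Passing `group` as
a confounder is refused outright.

Genomic inflation uses the classic genomic-control estimate
λ = median(χ²₁-quantile of observed p)/median(χ²₁); the Bayesian
Gibbs-sampler alternative is out of scope by design — λ fills the same
diagnostic role in closed form. The permutation null (default 20 shuffles of
the group labels, seeded) shows where λ sits when the group association is
destroyed while the correlation structure is kept; it concentrates near 1
regardless of the true effect. Surrogate-variable analysis is out of scope.

## Differential methylation

The moderated t-test follows the empirical-Bayes variance-shrinkage scheme:
pooled per-probe variance s² on d = n₁+n₂−2 df; prior df d₀ and prior
variance s₀² by moment matching on log s² — the spread of log s² in excess
of the trigamma(d/2) sampling contribution determines d₀ via Newton
inversion of the trigamma function (tolerance 1e−8, d₀ = ∞ when there is no
excess spread); posterior s̃² = (d₀s₀² + d·s²)/(d₀+d); two-sided p from t on
d₀+d df. Forcing d₀ = 0 recovers the ordinary pooled t exactly; d₀ = ∞
gives the fully pooled variance. The implementation matches Bioconductor
limma's eBayes (t, p, and prior df agree to ~1e−6 on random fixtures, tested
through Rscript). Zero-variance probes are handled by pooling — no division
by zero. log₂FC is the difference of group mean M-values, case − control.

BH adjustment is the standard step-up with the cumulative-minimum
formulation (deterministic under ties). Direction calls: p_adj < α and
log₂FC > 0 → hyper, < 0 → hypo, exactly 0 → none.

Gestational-DMR exclusion removes flagged probes from the *significant* set
after testing (the ambiguity of removing before vs after testing is resolved
in favour of after, keeping the tested universe fixed; filtering the matrix
before testing is available by simply dropping the probes first). Feature
composition of the significant set vs the background (per island relation
and per gene region) is summarised with a chi-square goodness-of-fit test
against the background composition, separately available for hyper and hypo
sets.

## Pathway enrichment and pathway scores

Enrichment is the plain upper hypergeometric tail
P(X ≥ k) = Σ_{i=k}^{min(K,n)} C(K,i)C(N−K,n−i)/C(N,n) over a
region-filtered universe (promoter by default, matching the marker-selection
and pathway-score usage). For N ≤ 1000 the sum is exact integer arithmetic;
above that it is computed in log-gamma space with max-factoring. Summing the
upper tail directly is numerically safer than 1 − lower-sum and is
algebraically identical. K = 0 pathways get p = 1 by convention and a flag.
BH runs across the pathways of one collection at a time. Probe-number bias
correction (Wallenius-type) is out of scope; per-pathway CpG counts are
reported so users can see the bias surface.

Pathway β-scores are per-sample unweighted means over the pathway's promoter
CpGs, compared between groups by a Wilcoxon rank-sum test: exact null
enumeration when n₁+n₂ ≤ 12 with no ties, otherwise the normal approximation
with tie correction and 0.5 continuity correction (agrees with
scipy.stats.mannwhitneyu to ~1e−6).

## Stemness

Entropy treats a sample's β vector as a distribution (p_i = β_i/Σβ;
0·log 0 ≡ 0), normalised by log N so the uniform profile scores exactly 1
and a degenerate profile exactly 0. Natural log is used internally; any base
cancels against log N (tested). β is used un-clipped here since no logit is
taken. The stemness score is the min-max scaling of entropy across the
scored cohort — **cohort-relative**: scores from separately scored cohorts
are not comparable. The probe universe is all retained post-filter probes,
not only the differential ones. Fewer than two samples, or a zero entropy
range, is an error rather than a silent 0/0.

## Methylation-expression integration

Gene-level methylation is the unweighted mean β over a gene's promoter
probes. Pearson correlations run across the explicit sample-ID intersection
of the two matrices (≥3 required). Expression fold change is
(mean case + 0.5)/(mean control + 0.5) — the pseudocount guards against
empty denominators; the package accepts any normalised expression matrix
and the correlations inherit that choice. Screening rules: PCC < −0.2 for
the enrichment candidate set; |FC| > 1.5 (FC > 1.5 or FC < 1/1.5) and
PCC < −0.3 for the top set. Zero-variance genes are flagged undefined and
excluded from selections.

## Marker panel and transfer classification

Markers are the significant, hypermethylated, promoter-region CpGs of genes
in the union of the top-k (default 5) enriched pathways, ranked by p_adj
(ties: p_raw, then name), optionally intersected with an external platform's
probe set; an empty panel raises an error that names the filter that emptied
it, and the panel size is always data-driven. The classifier consumes β
rather than M: bounded features transfer across cohorts without per-cohort
variance rescaling. Random forest defaults: 500 trees, √p features per
split, unlimited depth, seeded. Training uses a stratified 80/20 split with
5-fold CV on the training portion; both CV and hold-out metrics are
reported (they answer slightly different questions), and the transfer model
is refit on all cohort samples. Transfer requires every marker present in
the external matrix — the availability filter at selection time is the
supported way to guarantee this. Metrics: accuracy, balanced accuracy
(mean of sensitivity and specificity; invariant to class prevalence), F1
with the tumor/case class positive, and trapezoid AUC over the unique-score
threshold sweep (identical to the Mann–Whitney U/(n₁n₂) rank form, tested
to 1e−12).

## Synthetic cohorts: what they emulate, and what they do not

Defaults are the study conditions: 38 controls vs 34 cases, 10,000 CpGs,
1,000 genes, 5% of CpGs affected at Δβ = +0.15, categorical and continuous
clinical confounders at M-scale effect sizes 0.3–0.4, two slide/array
batches (additive M-shift sd 0.3, noise scale ratio 1.1), promoter
expression coupling ρ = −0.5, and an external two-class cohort sharing a
+0.2 marker shift. Per-probe baseline mean β comes from a Beta(3,17) /
Beta(17,3) mixture (modes ~0.15 / ~0.85) to mimic the bimodal 450K density;
promoter probes take the hypomethylated mode with probability 0.85 (as real
promoters do), which also keeps the case shift clear of the 0.99 clip.
Per-sample variation is Gaussian on the M scale (sd 0.35, a mid-range 450K
probe dispersion); confounder and batch effects are additive on the M scale
(where adjustment operates) while the group effect is additive on β
(interpretable Δβ), clipped into (0.01, 0.99) with a warning.

Truth CpGs sit preferentially (80%) in promoter probes of a designated
truth-gene set, the remainder in those genes' non-promoter probes or
intergenic probes — so the genes hosting planted CpGs are exactly the truth
genes, and the truth pathways (which absorb them, padded with decoy genes)
contain every gene hosting planted signal. Decoy pathways draw only from
non-truth genes so a decoy can never enrich through planted signal; real
KEGG collections overlap more promiscuously than this. Every seeded
operation is bit-reproducible.

Not emulated: probe-type chemistry (no BMIQ), .idat intensities, cell-type
composition, spatial/chromosomal correlation between neighbouring CpGs,
multi-gene probes, missing values, or realistic pathway overlap. Passing
tests therefore demonstrate the statistical machinery — calibration under
the null, recovery of additive planted effects at the study's sample size,
correct bookkeeping — not robustness to every artefact of real arrays.

## Problem sizes and tolerances in the test suite

The suite exercises cohorts of 1,200–10,000 CpGs (the full 10,000 × 72
conditions appear in the calibration and recovery checks and in the
acceptance script; smaller sizes where only bookkeeping is at stake).
Numerical tolerances: exact combinatorial identities at 1e−12, OLS/projection
properties at 1e−8–1e−10, reference-implementation agreement at 1e−6
(limma) and a few percent of spread (the batch adjuster, whose variance
convention deliberately differs), calibration bands as stated per test.
Determinism is asserted byte-for-byte on all pipeline artifacts (fixed
float formatting, sorted JSON keys, stable sorts everywhere ties can occur).

## Known limitations

* The residual-based confounder adjustment can absorb group signal when
  confounders correlate with group; λ is reported, interpretation is left
  to the user.
* Stemness scores are cohort-relative by construction.
* The hypergeometric enrichment ignores per-gene probe-count bias.
* The synthetic generator's independence assumptions (probes independent
  given factors, decoy pathways disjoint from truth genes) make recovery
  cleaner than on real data; reported recall/FDR characterise the machinery
  under the stated model, not field performance.
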