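# methylseed

Analysis toolkit for Illumina 450K-style DNA methylation studies of
umbilical-cord hematopoietic stem cells (or any two-group EWAS cohort):
confounder detection and adjustment, differential methylation with
gestational-DMR exclusion, hypergeometric pathway enrichment, Shannon-entropy
stemness scoring, methylation–expression correlation screening, and a
hypermethylated-marker random-forest classifier transferable to external
tumor/normal methylomes. A first-class synthetic-data module generates
450K-like cohorts with planted, recoverable structure, so every stage can be
exercised and validated without any data download.

## The statistics at the core

* **β and M values.** Per CpG, β = methylated/(methylated+unmethylated)
  intensity ∈ [0,1]; M = log₂(β/(1−β)) is used for linear modelling.
* **Source-of-variation screen.** Per probe, one linear model over all
  clinical factors; each factor's marginal (type-III) F is averaged over
  probes. Factors with mean F > 1 (the error reference) are confounders and
  are removed by OLS residualisation. Genomic inflation
  λ = median(χ²₁-quantile of p)/0.4549 and a permuted-label null λ
  distribution diagnose calibration.
* **Moderated t-test.** Per-probe variances are shrunk toward an
  empirical-Bayes prior (d₀, s₀²) estimated by moment matching on log s²
  (trigamma inversion); t = Δ M̄ /(s̃√(1/n₁+1/n₂)) with d₀+d degrees of
  freedom, BH FDR across probes, hyper/hypo calls by the sign of the
  M-value log₂ fold change (case − control).
* **Pathway enrichment.** For a pathway with K CpGs out of an N-CpG promoter
  universe and n significant CpGs overall, P(X ≥ k) is the upper
  hypergeometric tail Σᵢ C(K,i)C(N−K,n−i)/C(N,n), BH-corrected across
  pathways.
* **Stemness.** A sample's β profile is normalised to a distribution
  p_i = β_i/Σβ; Entropy = Σ −p_i log p_i / log N ∈ [0,1] and the stemness
  score is the cohort-relative min-max scaling of entropy.
* **Transfer classifier.** Significant hypermethylated promoter CpGs of the
  genes in the top-5 enriched pathways become a marker panel; a 500-tree
  random forest is trained with a stratified 80/20 split and 5-fold CV, then
  refit and applied to an external two-class β matrix, reporting accuracy,
  balanced accuracy ((sens+spec)/2), F1, and AUC.

## Worked example

Run the whole pipeline on a synthetic cohort from one config:

```bash
methylseed all --outdir run --seed 1
```

or equivalently from Python:

```python
from methylseed.pipeline import run_pipeline
report = run_pipeline({"seed": 1, "simulate": {"n_cpg": 3000, "n_gene": 300}},
                      outdir="run")
print(report["stages"]["dm"])
print(report["stages"]["enrich"]["top"])
print(report["stages"]["classify"])
```

which prints (3,000 CpGs, 38 controls vs 34 cases, 5% of CpGs shifted by
Δβ = 0.15 in cases):

```
{'status': 'ok', 'n_hyper': 155, 'n_hypo': 3, 'n_in_dmr': 21,
 'n_excluded_from_significant': 0, 'n_missing_coordinates': 0,
 'island_fraction': 0.2848101265822785}
['PATHWAY001']
{'status': 'ok', 'n_markers': 123, 'holdout_balanced_accuracy': 1.0,
 'transfer_balanced_accuracy': 1.0}
```

Reading: of the 150 planted CpGs, 155 probes come out significant at BH FDR
< 0.05 and the hypermethylated calls vastly outnumber the hypomethylated
ones (155 vs 3), as designed; the planted pathway is the top enrichment hit;
the marker panel (123 hypermethylated promoter CpGs from the top pathways)
classifies the held-out cohort samples and an external shifted cohort
perfectly. Each stage directory under `run/` contains its TSV/JSON artifacts
plus a `manifest.json` with the seed and sha256 checksums; rerunning with
the same config reproduces every file byte-identically.

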