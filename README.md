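# bimodalkit

Genome-wide detection of **bimodally expressed genes** in tumor expression
cohorts, and a survival screen asking whether patients in the two expression
modes have different prognosis.

A gene is *bimodal* when its expression distribution across a cohort has two
maxima — two subpopulations of samples in distinct expression states. Such
genes are natural biomarker candidates: each mode can correspond to a
phenotypic state, and comparing survival between the modes can reveal
clinically meaningful stratifications. `bimodalkit` is aimed at
bioinformaticians analyzing bulk RNA-seq cohorts (e.g. TCGA FPKM matrices
with cBioPortal clinical tables), and works equally on any gene × sample
matrix of non-negative expression values.

## The method

Per gene, a three-step screen configured by seven parameters:

1. **Peak detection.** The expression density f̂(x) is estimated with a
   Gaussian kernel on a 512-point grid using Silverman's rule-of-thumb
   (nrd0) bandwidth h = 0.9·min(σ̂, IQR/1.34)·n^(−1/5). The first derivative
   f̂′(x) is smoothed with a GCV-penalized cubic spline; sign changes of
   f̂′ mark peaks (+→−) and valleys (−→+). Peaks below
   *thresholdDown* = 20% of max f̂ are pruned, and adjacent peak/valley
   pairs differing by less than *thresholdUp* = 10% of max f̂ are merged.
   The surviving peak count is *k*.
2. **Clustering.** For k = 2, a univariate Gaussian mixture with k+1
   components is fit by EM. The extra component absorbs samples with low
   affinity to the main clusters; its samples are discarded, as are samples
   whose assignment reliability (max posterior) is ≤ 46% and whole clusters
   holding < 10% of samples.
3. **Peak confirmation.** Step 1 is re-run on the retained samples; the gene
   is called bimodal only if two peaks persist. Retained samples are labeled
   peak 1 (lower mode) / peak 2 (higher mode).

Samples below *minExpression* = 0.02 FPKM are excluded up front, genes with
fewer than *minSampleSize* = 50 remaining samples are skipped, and an
optional log2/log10 transform (*useLog*) aids detection when the dynamic
range is wide.

For every bimodal gene, peak-1 and peak-2 patients are compared with
Kaplan–Meier curves and the two-group **log-rank test**
(χ² = (O₁−E₁)²/ΣVᵢ, 1 df), flagged at the 5% and 1% levels. Cross-cohort
summaries count bimodal genes per cohort and genes bimodal in several
cohorts, with a hypergeometric test for chromosome enrichment.

## Worked example

Simulate a 20-gene, 300-sample cohort (5 planted bimodal genes; survival
driven by the modes of the first one at hazard ratio 3), then detect and
screen:

```bash
bimodalkit simulate --n-samples 300 --seed 11 --hazard-ratio 3 --out sim
printf 'use_log = log2\nseed = 11\n' > cfg.txt
bimodalkit detect --expr sim/expression.tsv --cohort SIM --config cfg.txt --out det
bimodalkit survival --strat det/stratification.tsv --clinical sim/clinical.tsv --out surv
```

which prints

```
wrote synthetic cohort (20 genes x 300 samples) to sim
SIM: 5 bimodal genes of 20 analyzed
5 genes tested: 1 at p<0.05, 1 at p<0.01
```

All five planted bimodal genes are recovered (`det/bimodal_calls.tsv`
records their initial and confirmed peak locations and per-mode sample
counts), and the survival screen (`surv/prognosis.tsv`) flags exactly the
gene whose modes carry the hazard difference:

```
gene_id  n_group1  n_group2  events_group1  events_group2  chi_square  p_value      significant_01
BIM000   131       141       93             123            40.98       1.54e-10     1
BIM001   144       141       108            112            0.151       0.698        0
...
```

BIM000's peak-2 patients (higher expression, 3× hazard) die markedly faster
— log-rank χ² = 41.0, p = 1.5 × 10⁻¹⁰ — while the null bimodal genes stay
non-significant. The same operations are available as library functions
(`bimodalkit.analyze_cohort`, `bimodalkit.prognosis_screen`, …).

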