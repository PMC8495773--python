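# Methods

## Model and procedure

`bimodalkit` treats a bimodal expression distribution as a two-component
Gaussian mixture observed through a kernel density estimate. The screen is
deliberately two-stage: a *nonparametric* stage (KDE + derivative peak
calling) proposes the number of modes k, and a *parametric* stage (a k+1
component Gaussian mixture) assigns samples to modes and strips outliers
before the nonparametric stage re-confirms the call. The redundancy is the
point — a peak must survive both a smoothed-density criterion and a
mixture-based re-screen on filtered samples to count.

### Density estimation

The density is a Gaussian KDE evaluated by direct kernel summation on 512
equally spaced points spanning `[min − 3h, max + 3h]`, h being Silverman's
rule-of-thumb bandwidth

    h = 0.9 · min(σ̂, IQR/1.34) · n^(−1/5)

with the standard fallback chain when the spread estimate degenerates
(substitute `max(σ̂, IQR/1.34)`, then `|x₁|`, then 1). Quartiles use linear
interpolation (type-7). The rule-of-thumb selector is a deliberate choice
over more precise selectors (e.g. Sheather–Jones): it oversmooths slightly
and therefore only reacts to large density fluctuations, which is the
desired sensitivity for mode counting.

### Derivative smoothing and peak calling

The slope is the central finite difference of the density on the grid. When
smoothing is enabled (the default) a cubic smoothing spline with its penalty
chosen by generalized cross-validation is fit to the slope and evaluated
back on the grid. Because the KDE derivative at 512 points is heavily
oversampled, the spline is fit on a 4×-thinned subgrid (last point always
kept) and evaluated on the full grid; at these smoothness levels the result
is indistinguishable from the full fit at a quarter of the penalty-search
cost. An optional numeric penalty overrides the GCV choice.

Peaks are +→− sign flips of the slope, valleys −→+; a run of exact zeros is
collapsed to its midpoint, and within each flip's bracketing range the
extremum index is refined to the arg-extreme of the density. Grid endpoints
are never peaks. Pruning applies the *down* rule first (drop peaks below
`threshold_down × max density`, default 20%), then the *up* rule merges —
smallest gap first — any adjacent peak/valley pair whose height difference
is below `threshold_up × max density` (default 10%), keeping the taller
peak, leftmost on ties. Between two surviving peaks exactly one valley (the
deepest) is kept, so the output always alternates.

### Mixture stage

The univariate unequal-variance EM is deterministic by default: means start
at evenly spaced quantiles, weights equal, variances pooled. Convergence is
a relative log-likelihood change below 1e-6 (max 500 iterations); variances
are floored at `1e-6 · var(x)` to prevent collapse. Optional seeded
random-jitter restarts are available but not needed in practice — on small
fixtures the deterministic fit matches the best of 200 random restarts
(checked against scikit-learn's `GaussianMixture` in the tests, which serves
as an independent oracle only and is never on the computation path).

Detected peaks are matched to fitted components greedily by nearest mean,
closest pair first, without replacement; the one unmatched component is the
"extra" cluster whose samples are discarded. A sample is retained only if
its maximum posterior is strictly above `min_posterior` (default 0.46 — a
deliberately lax reliability bar, since expression values are not truly
Gaussian and a stricter bar discards too many samples), and only if its
cluster holds at least `min_cluster_frac` (default 10%) of the
post-expression-floor sample count. The cluster-size rule is evaluated on
raw cluster membership, before the reliability rule, so that lowering
`min_posterior` can only grow the retained set.

### Confirmation and stratification

The confirmation re-runs the full detection — including a freshly computed
bandwidth — on the retained samples. Only a confirmed two-peak gene is
called bimodal; genes with ≥ 3 initial peaks are recorded as non-bimodal
(the screen pursues two-mode structure only), and genes whose second peak
vanishes after filtering get status `rejected_confirmation`. Peak 1 is
always the lower-expression mode. Per-gene seeds derive from the global seed
plus a CRC32 hash of the gene id, making results independent of gene order.

### Survival screen

Only labeled peak-1/peak-2 patients enter the survival comparison — samples
discarded by the mixture filters are excluded, on the view that unreliable
mode assignments would dilute a real prognosis signal. Kaplan–Meier
estimation and the two-group log-rank test are computed with `lifelines`
behind this package's record types; censored subjects at an event time
remain at risk for that time (standard convention). Raw p-values are flagged
at 5% and 1% with no multiple-testing correction by default, since the
screen reports per-gene significance counts; Benjamini–Hochberg adjustment
is available behind a flag. Clinical-to-expression sample matching trims
whitespace and can compare barcode prefixes (first N characters) to
reconcile sample- vs patient-level TCGA identifiers; clinical times are
days, with a months→days (×30.44) conversion option.

### Chromosome bias

Enrichment of a gene list on one chromosome is a hypergeometric upper tail:
the probability of drawing at least the observed number of
target-chromosome genes when sampling the foreground size from the
annotated background. The choice of test is this package's own; it is the
natural exact null for "more Y-chromosome genes than expected".

## Synthetic data: what it emulates, what it does not

The generator draws each gene log-normally per mode — positive support and
right skew, matching FPKM's gross shape — with the two modes of a bimodal
gene separated on the ln scale. Defaults encode the study conditions used
throughout the tests: within-mode ln-scale sd 0.4 (so "5σ separation" means
a ln-mean gap of 2.0, i.e. a ~7.4× fold change), equal mode weights,
cohorts of 200–500 samples, and a noise-floor gene class mostly below
0.02 FPKM. Detection runs on the log2 scale, exercising the `useLog` path,
where each mode is exactly Gaussian. Survival times are exponential with a
mode-dependent hazard and uniform censoring on [0, T], T solved numerically
for the requested censored fraction.

Real cohorts differ in ways the generator does not model: library-size and
length biases, count-level noise (negative binomial rather than log-normal),
tumor purity and cellular heterogeneity, correlated genes, and
non-proportional hazards. Passing tests therefore demonstrate that the
screen recovers planted two-mode structure and calibrated survival
significance under clean mixture conditions — not that any particular real
gene list is correct.

## Numerical choices and scales

- Grid: 512 points, 3-bandwidth cut — the conventional density-routine
  defaults the screen's thresholds are calibrated against.
- Reliability cutoff is a strict inequality (posterior > 0.46 retained).
- Ties in the up-rule merge keep the leftmost of two equal-height peaks, so
  output is deterministic.
- Constant-expression genes (zero range after filtering) are unimodal by
  definition; a retained set smaller than two samples rejects confirmation.
- Test problem sizes (200-gene cohorts, 100–1000 replicate calibrations,
  12-cohort separation sweeps) were chosen as the smallest sizes at which
  the binomial noise of the measured rates is well inside the asserted
  margins.

## Known limitations

- k is taken from peak detection; no information criterion reconsiders it.
- The mixture is strictly univariate Gaussian with unequal variances; no
  model-family selection.
- The log-rank test is unstratified and unadjusted (no Cox covariates); the
  screen flags association, not causation.
- Multi-modal (k ≥ 3) genes are reported but not pursued.
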