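# Methods

This note records the models the package implements, the conventions and
defaults it fixes where the underlying procedures leave room, and what the
synthetic benchmark does and does not emulate.

## Study design assumed

A continuous-culture (turbidostat) experiment: K growth media, each run in
three biological replicates, each culture at a steady-state growth rate μ
measured by fitting an exponential to OD readings taken every 30 s during a
regrowth phase (`quantify.estimate_growth_rate` is the least-squares slope
of ln OD vs time).  The default emulated design is 8 conditions × 3
replicates with condition-mean growth rates evenly spaced over 0.05–0.28
h⁻¹ and a 2% lognormal replicate jitter.  Transcripts are quantified as
raw gene counts; proteins as iBAQ intensities with molecular masses.

## Units

- normalized counts `n = c/S`, with size factors S from the
  median-of-ratios method restricted to genes with nonzero counts in every
  sample (the standard convention; the procedure itself only names the
  method).
- proteome mass fractions `φ_i = m_i B_i / Σ m_l B_l`; proteome number
  fractions `ψ_P = B_i / Σ B_l`; transcriptome number fractions
  `ψ_M = (n_i/l_i) / Σ (n_l/l_l)` with transcript lengths l.  Fractions
  sum to one per sample over the included genes; zeros/missing values
  contribute zero to the denominators and propagate as zero/missing
  fractions.
- z-scores use the sample (n−1) standard deviation; constant rows are an
  error (or dropped with a warning under a flag).

## Growth laws

**Estimator.**  The repeated-median linear model: for point *i*, the
pairwise slopes `(y_j − y_i)/(μ_j − μ_i)` and intercepts
`(μ_j y_i − μ_i y_j)/(μ_j − μ_i)` to all other points are reduced to
per-point medians, and the fit is the median over points (midpoint
convention for even counts; pairs with |Δμ| < 1e-12 are excluded from a
point's medians; a gene needs ≥ 3 finite points and ≥ 2 distinct μ).  The
breakdown point near 50% is what makes the fit robust to
condition-specific induction, where a whole condition (3/24 points) is
displaced coherently.

**Fold change.**  `FC = μmax/(0.5 μmax + b/a)` with μmax = 0.3 h⁻¹, equal
to `(y(μmax) − y(0))/y(μmax/2)` on the fitted line; FC is invariant to
rescaling y, 0 for a flat line, undefined (NaN) when the mid-growth value
is zero.

**Fit statistics.**  `R² = 1 − SSR/SStot` from the robust-fit residuals
(may be negative), `SSRnorm = SSR/((N−1)·ȳ)`, and a p-value from the upper
tail of F(1, N−2) at `F = max(R²,0)/(1−max(R²,0))·(N−2)`.  A robust fit
has no exact finite-sample F theory; this is the closest well-defined
analogue of the usual regression summary and is conservative under the
null, because the repeated-median residual sum of squares is at least the
least-squares one.  `R² ≤ 0` maps to p = 1.

**Sectors.**  Tail-based fdr (q) and local fdr are computed from the
per-gene p-value distribution (below); q < 0.1 with a positive slope gives
R, with a negative slope P, all else Q; local fdr < 0.1 flags confident
calls.

**fdr machinery.**  A two-component model for p-values: the null
proportion η₀ is estimated by censoring at λ = 0.5
(`#{p > λ}/((1−λ)n)`), the tail-based fdr is `η₀·p/ECDF(p)` with a
monotone correction (exactly Benjamini–Hochberg when η₀ = 1), and the
local fdr is η₀ divided by the Grenander density (slopes of the least
concave majorant of the p-value ECDF).  The emulation reproduces the
structure of the standard two-component machinery, not any package's
numerics; with fewer than 50 p-values it falls back to BH with a warning.

**Bootstrap bands.**  Case resampling of (μ, y) pairs, refit per resample,
2.5/97.5-percentile envelopes of the predictions on a 101-point grid over
[0, 0.3] h⁻¹; FC is reported as mean ± sd over resamples; resamples with
fewer than two distinct μ are redrawn and counted.

## Unsupervised structure

Clustering is Ward linkage in the ward.D2 convention (squared Euclidean
distances inside the Lance–Williams update) on z-scored rows; the cluster
count k is a user parameter.  PCA treats genes as observations (rows are
already centered by z-scoring; no further scaling); each PC is oriented so
its largest-magnitude sample coordinate is positive, making downstream
labels reproducible.  A gene's PC1 variance fraction is
`score₁²/‖z‖²`; genes with more than 50% of variance on PC1 are labelled
`plus`/`minus` by the sign of their correlation with the PC1 sample
pattern (the condition-mode, WFSP-type classification).  Barcode lengths
are `(x − M)/M` with x the per-condition replicate median and M the
overall median, missing data imputed to zero first, clamped to [−1, 2];
genes with M = 0 are flagged undefined.

## Cross-omics comparison

All correlations act on log₂ number fractions over the genes detected
(finite, positive) in all six samples of a condition; the universe size is
reported per condition.  Reliability r is the geometric mean of the three
pairwise replicate Pearson correlations; the raw protein–mRNA estimate ρ̂
is the geometric mean over the six unordered replicate pairs (the three
matched pairs plus the three cross pairs); the corrected estimate is
`R = ρ̂/√(r_P r_M)`, reported unclamped with a flag when |R| > 1.
Non-positive pairwise correlations make the geometric mean undefined and
raise an error with the offending values rather than taking complex roots.
The residual protein-to-mRNA ratio subtracts each gene's median log₂
ψ_P/ψ_M across samples, removing the expression-level-dependent
amplification trend so between-sample differences are comparable across
genes.

## Growth-rate-removed differential expression

The aim is to call expression changes a condition causes *beyond* the
growth-rate trend.  Per gene, the growth-law fit predicts normalized
counts `p(μ) = aμ + b` and raw counts `q = p·S`; the recorded
normalization factors `N = n/p` are rescaled to a per-gene geometric mean
of one, genes with any non-positive prediction are excluded and listed,
and the synthetic reference condition takes, per replicate, the integer-
rounded median of q across conditions.

The NB test itself is a deliberately simplified DESeq2-style analogue with
three considered deviations:

1. **Exposures are model predictions, and leave-one-condition-out.**  The
   GLM models counts as NB with exposure equal to the predicted raw
   counts, so the fitted group levels are observed/predicted residuals and
   the condition-vs-reference contrast is growth-trend-free by
   construction.  For the tested condition the prediction comes from a
   repeated-median refit that excludes that condition's own samples:
   with the full fit, a genuine condition effect drags the prediction
   toward itself and attenuates its own fold change by ~10–15%.  The
   recorded normalization quantities (p, q, N, reference) remain full-fit.
2. **The Wald variance adds the prediction uncertainty.**  The fitted line
   is an estimate; its error moves a condition's residual coherently
   across replicates, most strongly at the ends of the growth-rate range
   and for steep negative growth laws (small predicted levels there are
   differences of large noisy numbers).  The added term is the
   heteroscedastic linear-theory variance `Σ w² VarNB` at predicted
   levels, times an efficiency factor (default 2.25) calibrated so that
   pure-growth genes' null z-scores have unit spread in simulation —
   smaller factors were measurably anti-conservative, larger ones
   conservative.  The reference level is a deterministic construct
   (medians of predictions, no sampling noise) and contributes no
   variance.
3. **Dispersions** are gene-wise Cox–Reid-adjusted profile-ML on a
   log-spaced grid, shrunk to the geometric midpoint with a fitted
   `α(m) = c₀ + c₁/m` mean–dispersion trend (the trend covariate is the
   expression level, not the residual scale); reference columns are
   excluded from estimation since they carry no biological noise.

Wald p-values (normal) are BH-adjusted within each contrast.  Fold
changes are shrunk with a zero-centered heavy-tailed (Cauchy) prior whose
scale is moment-matched per contrast; the posterior mode is found from
the exact cubic stationary equation and the global mode is selected, so
noisy fold changes collapse toward zero while decisively determined ones
pass nearly unshrunk.  (A normal prior was rejected: with sparse effects
it shrinks true log₂ fold changes of 1 below the calling threshold.)  A
gene is DE at `p_adj < 0.01` and `|log₂FC| > 0.5` (strict inequalities;
shrunk fold change by default, raw under a flag) in at least one
condition.

The one-way ANOVA variability screen (conditions as groups, Holm
step-down across genes, family-wise 0.05) is provided as the descriptive
entry point: it asks whether a gene varies across conditions at all,
before the growth trend is removed.

## Synthetic benchmark

The generator plants the structure the analysis assumes: growth dependence
lives on relative abundances (the scale the fits operate on); slopes and
intercepts are parameterized by target FC and mid-growth level
(`a = m·FC/μmax`, `b = m(1 − FC/2)`), so noiseless data reproduce the
planted parameters exactly.  Defaults, chosen once: sectors 30/25/45%
R/P/Q with |FC| ~ U(0.5, 2); mid-growth levels lognormal (σ_ln = 1.8);
20% of genes get a ±U(0.5, 1.5) log₂ offset in one random condition (an
optional mode plants a bimodal offset over a fixed half-split of
conditions, emulating a condition-specific expression mode); RNA counts
are NB with lognormal dispersions around 0.05 and lognormal library
depths (15% sd, ~600 expected counts per gene); protein intensities are
lognormal with CV 0.35 and Bernoulli detection (85% of genes fully
detected, the rest at 0.5–1).  The noise defaults were set so that
replicate reliabilities land in the high-90s% for mRNA and low/mid-90s%
for protein, the regime the correction is designed for.  Dispersion
exactly 0 is a documented noiseless switch (counts equal rounded means);
an NB with dispersion → 0 would still be Poisson.

What the generator does *not* emulate: sequencing is not compositional
(library scale is independent of the expression changes, so there is no
closure-induced anticorrelation); no peptide-level or ionization effects
behind iBAQ, no shared-peptide protein groups; no batch or run-order
structure; replicate noise is independent across genes.  Passing the
recovery tests therefore demonstrates correctness of the estimators under
the assumed model, not robustness to those real-data artifacts.

## Problem sizes in the test suite

The suite exercises recovery at 2,000 genes (sector assignment), 100-seed
recovery of a planted cross-omics correlation of 0.8 at 600 genes per
seed, three 400-gene DE calibration data sets (200 pure-growth genes at
the generator's mean |FC| of 1.5 plus 200 single-condition effects of
log₂ 1 at ~500 mean counts, planted in the six interior conditions),
200-dataset bootstrap coverage at 200 resamples, and a 5,000-gene /
2,000-protein end-to-end run executed twice and compared byte-for-byte.

## Known limitations

- At the two extreme growth conditions the leave-out prediction is an
  extrapolation; per-condition DE sensitivity there drops to roughly half
  that of interior conditions.  Effects at interpolated growth rates are
  the designed use case.
- The F-type p-value for the robust fit is an analogue, not exact theory;
  it is conservative under the null, which costs a little sector
  sensitivity near the threshold.
- The tail/local fdr machinery is a structural emulation of the standard
  two-component approach; numbers can differ from any specific package in
  the second decimal.
- Absolute molecule numbers per cell are not computed anywhere; all
  statements are about relative abundances, and total-pool scaling with
  growth rate is outside the model.
- Figure rendering is not included; all outputs are tables, and plotting
  is left to the caller.
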