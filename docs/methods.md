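# Methods

`phenostruct` quantifies population structure from tables of linear cranial
measurements: how much morphological variance lies *within* skeletal series,
and how much of the total is apportioned *between* them. This note documents
the statistical model, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Data model

The unit of analysis is a *series*: a skeletal collection treated as a
population sample, measured with up to 23 standard Howells linear variables
(GOL … OCC, in mm). Tables carry an explicit missingness mask; sexes are
pooled throughout (archaeological series are too small to split), which is
known to inflate within-series variances by the dimorphism component — see
the generator section below, where this inflation is made exact.

## Regression imputation

Missing cells are filled one at a time by ordinary least squares: the
missing variable is regressed on the variables that individual *does* have,
trained on complete cases within the individual's own series (default) or
the pooled sample. Small series rarely support the full predictor set, so
predictors are ranked by absolute pairwise-complete correlation with the
target and the set is shrunk until the training sample has at least
`max(k + 2, 3k)` rows for `k` predictors. The `3k` floor matters: designs
with only one or two residual degrees of freedom produce wildly
extrapolated fits that are worse than mean substitution, which defeats the
purpose of imputation. If no predictor set is supportable, the scope mean
of the variable is substituted (logged). Imputation is idempotent and never
touches observed cells.

Single-value regression imputation has a known side effect: imputed cells
sit exactly on the fitted regression surface and carry no residual
variance, so a series' covariance trace is deflated roughly in proportion
to its missing rate. The matched-n variance comparisons should be read with
this in mind for series with >10 % missing cells; propagating imputation
uncertainty (multiple imputation) is out of scope.

## Within-group variance

After Z-scoring every variable against the pooled reference (mean and SD
with denominator n − 1 over all individuals in the run), a series' scalar
variance summary is the trace of its covariance matrix (again ddof = 1).
With these conventions the pooled reference's own trace is exactly `t`, the
number of variables — a useful end-to-end check. Because a variance
estimate depends on n, a small series is compared against the distribution
of traces of random subsets of each larger reference series drawn *without
replacement* at the small series' n (default 1000 subsets, explicit seed).
Reference series smaller than the target contribute their full sample
(subset size clamped, flagged).

## Between-group apportionment (R-matrix Fst)

Group mean vectors m_i are compared through the codivergence matrix

    c_ij = (1/t) (m_i − x̄)ᵀ G⁻¹ (m_j − x̄),     G = h² W,

where W is the pooled (df-weighted) within-group covariance, h² the assumed
heritability (default 0.55, the conventional average for human cranial
dimensions; phenotypic Fst is a *minimum* estimate and h² only rescales
it), and x̄ = Σ w_i m_i the weighted grand mean (weights w_i = n_i/Σn_j by
default, equal weighting as an option). The apportionment solves
Fst = Σ w_i r_ii with r_ij = c_ij (1 − Fst)/2, giving the closed form

    Fst = c̄ / (2 + c̄),     c̄ = Σ w_i c_ii.

With one trait, two equal-n groups, h² = 1 and unit pooled variance this
reduces to Fst = d²/(8 + d²) for a mean gap d — the package's exact oracle.
Because deviations are whitened by W⁻¹, Fst is invariant to per-variable
affine rescaling of the raw measurements.

**Finite-sample correction.** Two biases affect the diagonal of c when
estimated from data:

1. *Sampling inflation* — each m_i is estimated from n_i individuals, which
   inflates c_ii by (1 − w_i)²/(h²n_i) + Σ_{j≠i} w_j²/(h²n_j) (under
   sample-size weights this collapses to the classical (1 − w_i)/(h²n_i)).
2. *Centroid deflation* — the grand mean is estimated from the same groups,
   which deflates the diagonal by the factor 1 − 2w_i + Σw_j².

`bias_correction=on` (the default) removes both: subtract the sampling
term, then divide by the deflation factor, after which Σ w_i c_ii is an
unbiased estimate of 2F/(1 − F) under the divergence model and the
estimator recovers the true apportionment in expectation (verified
closed-loop to within 0.01 at F ∈ {0, 0.1, 0.25}). With `correction=off`
the estimator is the plain contemporary-centroid form, appropriate when
reporting apportionment *of the observed array* rather than estimating a
divergence parameter. Negative corrected diagonals are truncated to zero by
default (Fst is a variance proportion); `keep` preserves them for
diagnostics.

**Standard errors** use a delete-one-trait jackknife: Fst is recomputed
leaving each trait out and SE = sqrt(((t−1)/t) Σ (Fst₍₋k₎ − mean)²). Traits
are the only resampling axis that needs no individual-level model; these
SEs measure stability across measurements, not sampling of individuals.

**Pairwise Fst** between every two series uses the *globally* pooled W
(small series give unreliable pair-specific covariances), the pair's own
weights and the pair's own grand mean, and is floored at zero so the matrix
is a valid dissimilarity. Regional Fst estimates instead recompute W from
the region's own series, so each region is scaled by its own within-group
covariance (a config flag selects the global-W variant).

## Ordination

The pairwise-Fst matrix is embedded in the plane with Kruskal non-metric
MDS: SMACOF majorization (Guttman transform) alternated with
pooled-adjacent-violators monotone regression of configuration distances on
the dissimilarity order, minimizing stress-1
√(Σ(d − δ̂)²/Σd²). Ties in the dissimilarities are handled by the primary
approach (within a tie block the monotone fit is unconstrained).
Initialization is classical (Torgerson) scaling plus seeded random
restarts (default 4); convergence when the stress improvement drops below
1e−6 or after 300 iterations. Because the stress-1 denominator moves with
the configuration, SMACOF theory does not guarantee monotone stress-1; the
implementation therefore stops — keeping the previous configuration — if
an iteration would increase it, so the recorded stress history is
non-increasing by construction.

Bootstrap confidence: individuals are resampled with replacement within
every series at the original n, the pairwise-Fst matrix and its NMDS are
recomputed, and each replicate is superimposed on the original
configuration by full Procrustes (translation, rotation, reflection and
scaling allowed — MDS orientation and scale are arbitrary). Replicates are
*not* re-imputed: the bootstrap operates on the completed table, which
slightly understates imputation uncertainty. Replicates with a singular
pooled W are dropped and counted. The Procrustes residual statistic is the
sum of squared differences normalized by the centered reference's norm
(identical to the classical disparity); two fully degenerate
configurations superimpose with statistic 0 by convention.

## Synthetic-data generator

The generator is the inverse of the estimator's model so the whole pipeline
can be tested closed-loop: group means are drawn
μ_i ~ MVN(μ₀, (2F/(1−F)) h² W₀) and individuals ~ MVN(μ_i ± δ/2, W₀), with
+δ/2 for males and −δ/2 for females, followed by MCAR masking at rate ρ
(re-drawn if a row would lose every cell). The proportionality constant
2F/(1−F) makes the corrected estimator exactly calibrated: its mean
diagonal estimates 2F/(1−F) and F = c̄/(2+c̄) is recovered in expectation.

The packaged covariance template has millimeter-scale variances (SDs ≈ 1.8
to 6.2 mm, magnitudes typical of adult crania) and a correlation structure
with a general size factor (baseline inter-trait correlation 0.3) plus
local AR-style structure (0.3 + 0.7·0.45^|i−j|) — linear cranial
measurements share a size factor, and a mean inter-trait correlation near
0.3 is typical for Howells-type data. Pooling sexes inflates the realized
within-group covariance to W₀ + δδᵀ/4 (verified at large n), which is
exactly the overestimation incurred by pooled-sex analyses of real series.

What the generator does **not** emulate: real craniometric allometry,
geographically structured (non-exchangeable) divergence, hierarchical
region/series structure, non-MCAR missingness, or measurement error.
Passing closed-loop tests therefore establishes the estimators'
correctness under their own model, not the realism of that model for any
particular skeletal sample.

## Analysis panel and problem sizes

The numbered drivers under `analysis/` run the three standard analyses on a
synthetic 27-series panel that mirrors a published study roster (sample
sizes 14–110, published sex counts and missing rates, regions), with series
means diverged to a worldwide apportionment of F = 0.276 under h² = 0.55 —
the study-scale conditions, fixed once. Note the generator's divergence is
*flat* (exchangeable series), so regional sub-panels of the synthetic data
fluctuate around the same 0.276 scale instead of showing the real data's
regional contrasts; two-series estimates (e.g. the early-period pair) have
very large sampling variance by nature. Calibration experiments use
K = 10 series of n = 100 with t = 23 traits and 200 replicates per
condition; matched-n variance distributions use 1000 subsets; ordination
bootstraps use 100 replicates. All seeds are explicit inputs split from one
master seed.

## Numerical conventions

- Covariance denominator n − 1 everywhere (series, pooled reference, pooled
  within-group W), making the trace-equals-t identity exact.
- W is inverted via Cholesky; a singular W raises an error advising
  variable reduction rather than silently pseudo-inverting.
- Z-score reference = pooled run by default, so traces are comparable
  across series.
- Imputed values are clamped to a tiny positive number in the pathological
  case of a non-positive fitted measurement (logged), preserving the
  table's positivity invariant.
- Sex codes normalize to {M, F, U}; unparseable codes become U with a
  warning (sex is metadata only — analyses pool sexes).
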