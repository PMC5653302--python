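# Methods

`soilrich` implements the full analysis chain behind a national-scale map
and predictive model of soil bacterial richness: per-sample 16S reads are
clustered into OTUs and normalized to a fixed depth; per-site richness is
mapped by ordinary kriging under a fitted Matérn variogram and validated
through standardized squared prediction errors; ecological drivers are
attributed by variance partitioning over soil, land-use, climate,
geomorphology and PCNM spatial-descriptor groups; and a polynomial model
predicts richness from a handful of routinely measured soil covariates.
A synthetic survey generator reproduces the study conditions with known
ground truth, so every stage is testable without access to survey data.

## Synthetic survey generator

The generator emulates a systematic national soil-monitoring design:
sites at the centers of a 16-km grid over a 740-km square (~5.5·10⁵ km²),
jittered uniformly by up to 4 km. Land-use classes (forest, cropland,
grassland, perennial, other) are drawn with one multinomial at weights
proportional to 492/740/464/36/36. Those published per-class counts sum to
1,768 while 1,798 sites enter the analyses; the generator treats the
weights as proportions and leaves `n_sites` free (default 1,798).

Covariate marginals follow the survey's summary statistics: truncated
normals for pH and mean annual temperature, truncated log-normals for the
right-skewed chemistry (organic carbon, carbonates, available P, CEC,
metals), all bounded by the reported minima/maxima. Medians match the
reported medians; log-scale spreads are set from the reported quartiles
(σ = ln(Q3/Q1)/1.349). Sand closes the texture triple to 1000 g/kg and
total N is derived from organic C and the drawn C:N ratio, so
compositional and stoichiometric identities hold exactly. Dependence is
imposed through a Gaussian copula; the defaults encode the classic
confounding of the system — pH negatively associated with organic carbon,
and forests concentrated on acidic soils (land-use assignment is ordered
by a latent score correlated with the pH latent, with multinomial class
counts preserved exactly).

Synthetic richness is built as an exact three-part sum, stored separately:

* a deterministic polynomial of the covariates with the same functional
  form as the reference predictive model ({1, pH⁴, Clay², Clay²·C:N,
  Clay³·C:N, (C:N)²·x}); the default coefficients were calibrated once
  against the default marginals so that the deterministic part has mean
  ≈1288 and sd ≈145 richness units,
* a mean-zero Gaussian field with the reference map model's Matérn
  structure (partial sill 0.27·207², κ = 0.5, φ = 111.6/ln 20 km),
  simulated by Cholesky factorization (diagonal jitter up to 10⁻⁸ of the
  sill before failing with the offending eigenvalue),
* white noise with sd 102.

Together these give richness with mean ≈1288, sd ≈207, range ≈550–2000,
and a variogram whose nugget ratio is ≈0.73 — the reported study
conditions. What the generator does **not** emulate: spatially structured
covariates (soil properties are exchangeable across sites given land use),
real pedological geography, climate fields, or sequencing depth/quality
artifacts beyond substitutions and homopolymer-length errors. Passing
tests therefore demonstrate correctness of the estimators under the
declared model, not robustness to real-survey pathologies such as
covariate spatial confounding.

Simulated reads are copies of homopolymer-free random centroids
(pairwise dissimilarity at least the configured divergence, verified with
the pipeline's own identity), with geometric rank-abundances (each OTU
keeps at least one read), per-base substitutions, and homopolymer
extensions — the dominant pyrosequencing error mode, and invariant under
the clustering identity by construction.

## OTU pipeline

Reads are dereplicated per sample (non-ACGT reads dropped and counted).
Clustering is abundance-greedy at 95% similarity: unique sequences in
decreasing global abundance (ties lexicographic), each joining the first
centroid in founding order with identity ≥ threshold, else founding a new
OTU. Identity is computed on homopolymer-collapsed sequences as matching
columns over alignment columns of a global unit-cost alignment (edlib);
the pair is lexicographically ordered first so the value is symmetric.
The convention (gap = one column, mismatch = zero matches) is a declared
choice — the original pipeline's exact formula is not published.

The singleton filter removes OTUs whose global count is 1 *and* whose
single read was a dereplication singleton (strict rule, using clustering
provenance); without provenance it falls back to the total-count-1 rule
with a warning. Depth normalization subsamples each sample to a fixed
depth (default 10,000) by a multivariate hypergeometric draw; shallower
samples are dropped and logged. Rarefaction curves average subsampled
richness over replicate draws; the accumulation curve averages cumulative
distinct OTUs over random sample orderings (default 1,000).

## Geostatistics

The empirical semivariogram is the Matheron method-of-moments estimator
on equal-width lag bins (default: 15 bins to half the maximum inter-site
distance). Parametric families: Matérn (κ profiled over {0.25, 0.5, 1,
1.5, 2.5}; half-integer κ uses the closed exponential forms), exponential,
gaussian, spherical, nugget. Two fitting routes:

* **WLS** — Cressie weights N(h)/γ²; trust-region least squares on log
  parameters with multistart. Two identifiability guards: the scale
  parameter is bounded by twice the lag cutoff (an effectively infinite
  range is indistinguishable from pure nugget), and fitted structure whose
  effective range falls below the first resolved lag is folded into the
  nugget.
* **ML** — Gaussian likelihood under a constant unknown mean, with the
  mean and total sill profiled out analytically so only the nugget
  fraction and range are optimized (Nelder–Mead, warm-started from the
  WLS fit); families compared by a parameter-penalized score.

The effective (practical) range is defined as the distance where the
structured correlation drops to 0.05; for the Gaussian family this is
√(ln 20)·φ ≈ √3·φ. The bundled reference map model is the Matérn with
effective range 111.6 km, nugget ratio 0.73, κ = 0.5, and total sill 207²
(the reported richness variance); the published fit does not disclose κ or
the absolute sills, so those two constants are the package's
completion of the model, chosen to match the reported richness sd.

Ordinary kriging solves the covariance-form system with a Lagrange
multiplier (weights sum to 1). Cross-validation uses the augmented-matrix
shortcut (the inverse of the [C, 1; 1ᵀ, 0] system yields every deleted
prediction and variance at once), verified in tests against per-site
refitted systems. SSPE θᵢ = (zᵢ − ẑ₋ᵢ)²/σ²₋ᵢ is ~χ²₁ (mean 1, median
0.455) under a valid model; the 95% envelope for the SSPE mean and median
comes from (default) 1,000 fields simulated from the evaluated model at
the data locations. A k-fold variant is provided (both leave-one-out and
10-fold summaries are quoted for the original analysis). Richness enters
untransformed, matching the original choice; a normality pre-check is
available. Map prediction masks cells beyond a configurable distance to
the nearest site (default twice the effective range).

## Spatial eigenvectors (PCNM)

The inter-site distance matrix is truncated at the largest
minimum-spanning-tree edge (guaranteeing graph connectivity; ≈16–23 km on
the jittered grid), with beyond-truncation distances replaced by 4t;
−½D² is double-centered and eigen-decomposed; positive-eigenvalue
eigenvectors (orthonormal, centered) are the spatial descriptors.
Moran's I uses the row-standardized within-truncation connectivity;
one-sided permutation p-values (default 999 permutations) select
descriptors with significant positive autocorrelation at α = 0.001.

Each descriptor's scale comes from the practical range of a
Gaussian-family variogram fitted to it, classified into coarse
[110, 250] km, medium [60, 110) km, fine [30, 60) km (closed-left,
open-right; coarse's upper bound closed). Two situations yield
"unclassified": a range outside every band, and absence of resolvable
structure (a competing pure-nugget fit wins, or the structured fraction of
the fitted sill is under 20% — white-noise vectors otherwise draw
arbitrary ranges from flat variograms).

## Variance partitioning

All quantitative responses and predictors are standardized; land use
enters as indicator contrasts. Environmental variables are selected in
two steps: exhaustive best-subset enumeration (p ≤ 20; Gram-matrix
updates) scored by BIC and adjusted R², then forward selection over the
union of the two winning subsets, maximizing adjusted R² under the double
stopping rule (candidate p-value above α, or adjusted R² exceeding the
full-pool model's). Spatial descriptors are then forward-selected on the
environmental-model residuals; their orthonormality makes each
contribution equal its squared correlation with the residuals, which the
implementation checks internally.

Explained variance is Ezekiel-adjusted R²; with a univariate response,
redundancy analysis is exactly multiple regression, so all fractions are
computed from subset regressions. Unique and shared fractions follow by
Möbius inversion of h(T) = R²adj(all) − R²adj(all∖T); the sum of shared
fractions is reported under the label "interactions" without asserting
equivalence to any other decomposition. Fractions can be slightly
negative (an adjusted-R² artifact) and are reported unclipped. Marginal
significance uses Freedman–Lane permutation of reduced-model residuals
(default 1,000 permutations); stars follow P<0.01 **, P<0.001 ***.
Groups are free to contribute ~0 (geomorphology typically does).

## Predictive polynomial model

Candidate covariates are screened by iterative VIF elimination (drop the
largest until all ≤ 4) followed by pairwise |r| > 0.7 resolution (drop the
member with the larger mean absolute correlation); climate variables are
excluded by design and longitude stands in for them. The
calibration/validation split is Kennard–Stone max–min on standardized
covariates (90% → 1,618 of 1,798; ties to the lowest index); a purely
random splitter exists for comparison, but Kennard–Stone is the named
algorithm and is the default. Exhaustive subset search reports the best
model per size under BIC and adjusted R² with a membership matrix.

Polynomial designs are explicit term lists (products of powers, degree
≤ 5) fitted by OLS; aliased terms are dropped with a warning. BIC uses
the n·ln(RSS/n) + k·ln(n) convention with k counting the intercept,
slopes and error variance — recorded in every output, since published
BIC values are only interpretable up to convention. Diagnostics:
Shapiro–Wilk on residuals and Breusch–Pagan against the term design.
Sensitivity is the standardized regression coefficient per term,
SRC = (σ_X/σ_Y)·β̂, tabulated by |SRC| descending. Predictions evaluate
terms exactly and flag (never refuse) covariates outside the training
envelope.

The bundled reference model ships the published functional form with its
printed coefficients marked *provisional*: the printed equation carries an
orphan additive constant (folded into the intercept here) and evaluates
far outside the observed richness range at typical covariate values, so
the numbers are shipped as structure only and nothing numerical is
asserted on them. (The generator's default coefficients — same form,
rescaled — are the package's working replacement.)

## Problem sizes and numerical choices

Test and acceptance runs use the study's native scale where it matters
and smaller sizes elsewhere, as the package's own choices: parameter
recovery at 1,798 sites over 10 seeds (maximum-likelihood refit with the
reference smoothness, WLS warm start); SSPE calibration at 500 sites with
1,000 simulation-envelope draws over 5 replicates (the envelope excludes
a correct value 5% of the time, so the check allows one miss in five);
coefficient recovery on 600-site surveys over ≥40 seeds under white noise
(OLS standard errors assume independent errors; adding the spatially
correlated field would invalidate the 3-SE coverage being tested).
Cholesky factorizations add diagonal jitter up to 10⁻⁸ of the sill before
failing; kriging variances are clipped at zero; permutation p-values use
the (1 + exceedances)/(1 + permutations) convention.

## Known limitations

* The identity convention, Matérn κ grid, PCNM truncation rule and
  Moran connectivity are declared defaults where the original analysis is
  silent; results at those decision points are convention-dependent.
* Best-subset search is full enumeration (p ≤ 20); no branch-and-bound.
* No anisotropy, co-kriging, geodesy or cartography; coordinates are
  planar km supplied by the caller.
* The OTU stage targets the post-quality-control portion of the original
  pipeline: trimming, chimera removal and taxonomy-based singleton rescue
  are out of scope.
* Adjusted-R² fractions for forward-selected spatial descriptors should
  charge Ezekiel's correction with the candidate-pool size, not the
  selected size, to counter selection bias; `variance_partition` does so
  through its `pool_sizes` argument, which the caller must supply (other
  software typically uses the selected size and reports larger space
  fractions).
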