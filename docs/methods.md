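# Methods

This note documents the models, numerical choices and design decisions
behind `spectromicrobe`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and stage order

The pipeline mirrors a field-to-model analysis sequence: data ingest (or
synthesis) → spectral preparation → microbial response derivation →
core-to-plot aggregation and temporal alignment → association statistics →
ensemble PLSR retrieval. Defaults throughout follow the study design the
package models: ±60 d soil↔image alignment (inclusive) with ±120 d across
other tables, NDVI < 0.4 vegetation mask, 5000-read rarefaction, 5%
outlier removal over 200 screening runs, 70/30 calibration/validation
splits, 200 ensemble members, and 999 permutations for significance tests.

## Spectral preprocessing

* **Vector normalization** divides each spectrum by its full-spectrum
  Euclidean (L2) norm. The norm convention follows the standard
  vector-normalization practice in imaging-spectroscopy trait retrieval;
  it suppresses brightness differences from canopy shade while preserving
  spectral shape.
* **Index band lookup** uses the nearest grid band within 3 nm of the
  nominal wavelength (804/673 nm for NDVI, 860/1240 nm for NDWI); on a
  ~5 nm grid the nominal wavelengths are never exact. Indices are
  scale-invariant, so they may be computed before or after normalization;
  the pipeline computes them before band trimming so the red/NIR bands are
  always available.
* **Band trimming** keeps closed intervals 403–1334, 1450–1785 and
  1971–2396 nm (noisy and atmospheric-absorption bands removed).
* **Buffer averaging** includes pixels whose centres lie strictly within
  diameter/2 of the plot centre; ties at exactly the radius are excluded,
  which is deterministic and grid-independent. The buffer is a pure
  circle; no clipping to plot boundaries is attempted.
* Negative ingest reflectance (atmospheric-correction artifacts) is
  clipped to zero with a logged count.

## PLFA derivation

Biomarker membership: Gram-positive = {i14:0, i15:0, i16:0, i17:0, a15:0,
a17:0}; Gram-negative = {cyclo17:0, cyclo19:0}; Actinomycetales =
{10Me16:0, 10Me17:0, 10Me18:0}; saprophytic fungi = {16:1ω7cis, 18:2ω6,
18:3ω6}; AM fungi = {16:1ω5} (ASCII `w` replaces ω in code and files).
`total_plfa` sums every measured biomarker. The F:B ratio uses
(SF + AMF) / (G⁺ + G⁻ + Actinomycetales): the bacterial denominator
includes Actinomycetales because they are Gram-positive bacteria; the
membership tuples are module constants so an alternative convention can be
supplied. Ratios with zero denominators are flagged NaN rather than
raised, since downstream tables must tolerate them.

## 16S derivation

* **Undefined taxonomy** means a missing/blank label or one of
  {undefined, unclassified, unknown, na} at kingdom or phylum rank; such
  ASVs and all Archaea are removed before rarefaction.
* **Rarefaction** drops samples with strictly fewer reads than the depth
  and subsamples the rest without replacement via seeded
  multivariate-hypergeometric draws — exact rarefaction semantics,
  reproducible given the seed.
* **Dominant phyla** are those present in every sample *and* ranked in the
  top ⌈0.10·P⌉ phyla by mean relative abundance across samples (ties
  broken by total reads, then name); the ranking statistic is a documented
  choice — mean relative abundance — where pooled or median ranking would
  also be defensible.
* **NMDS** minimizes Kruskal stress-1 using SMACOF with isotonic
  (pool-adjacent-violators) monotone regression, best of 20 restarts
  (classical-scaling initialization plus random starts), maximum 300
  iterations, tolerance 1e-7. The final configuration is centred, rotated
  to principal axes and sign-fixed (first nonzero score on each axis
  positive) so orientation is reproducible.
* **CLR** uses multiplicative zero replacement with pseudocount defaulting
  to half the smallest nonzero relative abundance in the matrix.

## Core-to-plot aggregation

Hierarchical Bayesian plot averaging is approximated by a closed-form
empirical-Bayes normal–normal model: per variable, the within-plot
variance σ² is pooled across plots with ≥2 cores, the between-plot
variance τ² comes from a method-of-moments estimate
(var of plot means − σ²·mean(1/nᵢ), floored at zero), and each plot mean
is shrunk toward the unweighted grand mean with weights nᵢ/σ² versus 1/τ².
Single-core plots are therefore prior-dominated; τ² → ∞ recovers plain
means and τ² = 0 collapses to the grand mean, and every estimate lies
between its plot mean and the grand mean. ASV matrices are always
aggregated by simple means — per-ASV pooling is impractical at tens of
thousands of columns. Plain means remain selectable everywhere.

Temporal alignment treats the ±60 d window as inclusive and ignores
time-of-day. Among multiple qualifying years per plot, the year minimizing
the |soil − image| gap wins; ties go to the earliest year. Peak-greenness
and land-cover exclusions are modelled as upstream metadata flags — the
package does not compute phenology.

## Association statistics

* **Variation partitioning** computes RDA R² (trace of explained over
  total centred variance) for every non-empty subset of predictor groups
  and resolves all 2^g − 1 Venn-region fractions by inclusion–exclusion.
  Fractions use Ezekiel-adjusted R² — the standard community-ecology
  choice — with unadjusted fractions also reported; the unadjusted
  fractions plus residual sum to one exactly. Negative adjusted fractions
  are reported as-is with a zero-floored display column.
* **Partial RDA tests** residualize both response and focal block on the
  conditioners and permute the reduced-model residuals (Freedman–Lane),
  re-residualizing each permuted response; p = (1 + #{F* ≥ F})/(1 + n_perm)
  is never zero.
* **Partial Spearman** rank-transforms all variables (mid-ranks) and
  inverts the rank-correlation matrix; p-values use t with n − 2 − |Z| df.
  A singular correlation structure among the confounders raises an error;
  a pair made singular by full mediation is flagged degenerate. Note that
  rank-based partial correlation removes linearly acting confounders only
  approximately — the rank transform is nonlinear — so small residual
  partial associations can persist even under pure confounding.
* **Collinearity screening** mirrors the caret `findCorrelation`
  procedure: while any |ρ| ≥ 0.7 pair exists, drop the member with the
  larger mean absolute correlation. "Strongly correlated" is read as
  |ρ| ≥ 0.7.
* **Location** enters the climate group as latitude/longitude columns;
  land cover enters one-hot with a reference level dropped.

## Ensemble PLSR

* Single-response PLSR on mean-centred (not variance-scaled) predictors:
  vector-normalized spectra are already on a common scale, and unit
  scaling would re-weight absorption features. With one response the
  NIPALS weight vector is closed-form per component, and coefficients are
  accumulated per component count so one fit serves the whole PRESS curve.
* **PRESS selection** uses 200 random 70/30 splits of the calibration set
  and, by default, a one-standard-error parsimony rule about the PRESS
  minimum (the smallest component count within one SE of the minimum);
  a plain minimum rule is selectable. The parsimony rule drops to one
  component for pure-noise responses.
* **Outlier screening** runs before the calibration/validation split
  (matching the stage order above): each observation's MAE is averaged
  over its held-out appearances across 200 random 70/30 fits, and the top
  ⌊0.05·n⌋ observations are removed (ties broken by larger response value,
  then index). Observations never held out fall back to in-sample errors
  with a warning.
* **Uncertainty** is the sample SD over the 200 member predictions per
  plot. Negative predictions are returned as-is.
* **R²** is the squared Pearson correlation between observed and
  predicted (the prediction-plot convention); the one-to-one
  (Nash–Sutcliffe) R² is also emitted for transparency.
  NRMSE = RMSE / (max(obs) − min(obs)).
* All randomness flows from one master seed through
  `numpy.random.SeedSequence` spawning, recorded per stage.

## The synthetic-data generator

The generator emulates a continental plot network: ~15 ecoclimatic
domains carry 2-D latent environmental gradients; plots perturb the
domain gradient; cores add fine-scale noise. Foliar traits are linear in
the gradients plus trait-specific variation; soil, climate and land-cover
covariates derive from the same gradients.

Spectra are a smooth vegetation-like baseline plus seven Gaussian
absorption features (centres 490, 673, 980, 1200, 1660, 2100, 2300 nm —
all inside the kept band ranges) whose depths are linear in the traits,
a NIR structural plateau term scaled by an independent structure
covariate, and heteroscedastic sensor noise with SD = 0.5% of
reflectance. The feature-to-trait sensitivity matrix is fixed and full
rank, loosely following where pigments, water and lignin/cellulose absorb;
full rank matters because it keeps the trait vector identifiable from
spectra, which is what makes recovery of the planted signal a test of the
pipeline rather than of the generator. The visible-region baseline is
high enough that absorption depths never drive reflectance to the
non-negativity floor, keeping the trait→spectrum map linear at the
feature centres (saturated absorption would shift apparent importance to
feature shoulders, as it does in real chlorophyll bands).

Each planted microbial response is y = √s·η̂ + √(1−s)·ε on a realistic
PLFA scale, where η̂ is the empirically standardized planted predictor and
s is `signal_fraction`; realized predictor–response R² therefore matches
s up to sampling error. `confound_weight` interpolates the predictor
between purely direct trait effects (0) and purely shared gradient
effects (1). Read depths are uniform integers on (3000, 30000), deliberately
straddling the 5000-read filter. Core values are plot values plus noise
with SD = 0.15 of the response SD, giving the aggregation module a known
shrinkage target.

What the generator does **not** emulate: radiative-transfer physics (no
PROSAIL), spatial autocorrelation, phenology, nonlinear trait–reflectance
relationships, or fungal ITS data. Passing recovery tests therefore shows
the pipeline correctly extracts linear trait-mediated signal under
realistic noise — not that real canopies encode soil microbiota this
cleanly.

## Problem sizes

Recovery experiments use 300-plot studies (15 domains × 20 plots, 426
bands, 3 cores/plot) swept over 10 seeds; statistical-calibration checks
use 500 null replicates at n = 60 with 199 permutations (scaled down from
the 999 used for real analyses); oracle checks use 50 random small
problems. These sizes make the whole suite run comfortably on one CPU
while keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

* The empirical-Bayes aggregation is a stated approximation of full
  hierarchical Bayesian plot averaging (no MCMC, normal likelihoods,
  method-of-moments hyperparameters).
* NMDS is run on core-sample dissimilarities or plot-averaged matrices as
  supplied; no attempt is made to propagate rarefaction uncertainty.
* The PRESS one-SE rule is a documented choice; the original selection
  procedure it stands in for is not printed in full anywhere, and the
  plain-minimum rule is available where closer matching is wanted.
* Partial Spearman's incomplete removal of linear confounding (above) is
  inherent to rank-based partial correlation, not a bug.
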