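# Methods

This note records the statistical models implemented in `ndmap`, the
assumptions behind them, the design choices made where the methodology was
genuinely open, and what the synthetic cohorts do and do not emulate.

## Functional metrics

All metrics operate on parcellated BOLD series (vertices carry the raw
series; a region's series is the mean of its member vertices).

- **Signal variability.** `SV = sqrt(Σ (x_{i+1}−x_i)²)/(T−1)`. This differs
  from the textbook root *mean* squared successive difference,
  `sqrt(Σ d²/(T−1))`, by a factor `1/sqrt(T−1)`; both are exposed
  (`variant="printed"` default, `variant="rmssd"`). The two are proportional
  at fixed T, so downstream W-scores are identical whenever all subjects
  share a scan length; the choice only matters for mixed-length cohorts.
- **Regional homogeneity.** Kendall's W over a vertex's neighbourhood
  restricted to its own region (the vertex plus adjacent same-region
  vertices), then averaged within region. Ties get midranks; the mean rank
  R̄ is computed empirically (equal to K(T+1)/2 without ties). Series that
  are constant over time are rejected rather than silently ranked — their
  ordering is arbitrary and W would depend on tie policy. Isolated vertices
  are excluded with a warning.
- **Node strength.** Signed sum of Pearson correlations to all other
  regions — negative correlations are retained (no absolute value, no
  thresholding). The short/long split uses Euclidean distance between atlas
  centroids with a 75 mm cutoff; centroids are the only geometry the
  package carries, so distances are centroid-to-centroid by construction.
  `NS_short + NS_long = NS_full` holds exactly.

## Site harmonization (ComBat)

Parametric empirical-Bayes location/scale adjustment, one metric at a time:
feature-wise standardization after regressing out preserved covariates
(age, sex, diagnosis dummies) and batch means; method-of-moments priors
(normal on the location γ, inverse-gamma on the scale δ²) across regions
within batch; the usual iterated conditional posterior means for γ*, δ*².
The implementation is cross-checked in the test suite against Bioconductor's
`sva::ComBat` (agreement to ~1e-6 on shared inputs). Harmonization is fit on
all subjects jointly so diagnosis variance is preserved, and happens in
native (non-lateralized) space. Singleton batches and rank-deficient designs
are rejected. One caveat worth knowing: when a batch's offsets are nearly
identical across regions, EB shrinkage deliberately retains a small fraction
of the apparent shift (the prior cannot distinguish it from noise); with
region-varying offsets removal is essentially complete.

## Normative model and deviations

Per region, ordinary least squares on healthy controls with age and sex
(optionally mean framewise displacement for the head-motion sensitivity
variant). The residual SD uses the unbiased n−p denominator. W-scores are
out-of-sample residuals scaled by that SD; control W-scores are in-sample by
default (mean exactly 0, SD ≈ sqrt((n−p)/n)). Extreme deviations use the
inclusive rule |W| ≥ 1.96, matching the two 2.5% tails of a standard normal.

The multivariate composite is the per-region Mahalanobis distance of a
subject's (SV, ReHo, NS) W-vector from the control cloud. Because a distance
has no sign, the ±1.96 rule is given meaning by mapping D² through the
χ²₃ CDF and the standard-normal quantile, signed by the mean W across
metrics; the raw distance is returned alongside. Under the control
distribution this flags ≈5% of regions, consistent with the univariate rule.

## Connectome analyses

- **Neighbourhood deviation.** `p̄_i = (1/N_i) Σ_{j:C_ij>0} p_j C_ij` with
  N_i the count of connected neighbours. Note this divides by *degree*
  while weighting by connectivity — it is not a weighted mean; a
  `normalize="weights"` variant provides the weighted mean.
- **Spin nulls.** Per iteration a uniform random 3-D rotation is applied to
  the left-hemisphere sphere coordinates and its x-mirror to the right
  hemisphere; each rotated region takes the value of an original region by
  greedy one-to-one nearest-neighbour assignment (closest pairs first).
  Enforcing a true permutation (no donor duplication) keeps the value
  multiset intact, which the epicenter and coupling statistics assume; the
  spin literature varies on this point and the choice is deliberate.
  Subcortical regions have no sphere geometry and are uniformly shuffled
  whenever a full-brain map is permuted; maps that are entirely subcortical
  use pure label shuffles.
- **p-values** are one-sided with the (1+k)/(1+n) estimator, so they are
  never zero and remain valid (sub-uniform) under the null.
- **Epicenters.** Likelihood of region i = Spearman ρ between its
  connectivity profile (self excluded) and the prevalence map; significant
  regions (p < 0.05 against the permuted map) are ranked by descending
  likelihood. When subcortical profiles are correlated against a cortical
  map, the permuted object is still the cortical map, so spin nulls apply
  there as well.

## Structure–function coupling and dominance

OLS of the functional prevalence map on CT/FA/MD prevalence maps; fit is
reported as adjusted R², and the spatial significance of Spearman
ρ(empirical, predicted) comes from refitting on spun response maps. General
dominance averages each predictor's incremental gain over all 2^k−1 subsets.
The default gain currency is plain R²: adjusted-R² increments can be
negative, which would break the nonnegativity and sum-to-total properties
that make shares interpretable; an `adjusted=True` switch exists for the
alternative. With plain R² the unnormalized dominances sum exactly to the
full-model R² and orthogonal designs reduce to zero-order fits.

## Clinical evaluation

Linear hinge-loss SVM (liblinear) on standardized W-score features inside a
stratified nested 5×5-fold cross-validation; the inner loop grid-searches
the cost c ∈ {2⁻⁵ … 2⁵} (an RBF-width parameter would be inert for a linear
margin and is not searched). Scaling is fit on training folds only; the fold
audit log records train/test indices and the chosen c so leakage is
checkable. Each outer iteration pools decision values over its five test
folds into one AUC; the point estimate is the median over iterations with a
(2.5, 97.5) percentile interval. Permutation p-values refit the full nested
pipeline on shuffled labels (null replicates may use fewer outer iterations;
this is recorded). Features are focus-lateralized for diagnosis and outcome
tasks and kept in native space for lateralization (there the label *is* the
side). Interhemispheric contrasts are one-sided paired t-tests (positive t =
more ipsilateral load) with Benjamini–Hochberg correction across lobes
within subgroup; deviation counts are related to disease-course variables
with Pearson/Spearman correlations and a Welch t-test across the FBTCS
split.

## Synthetic cohorts

The generator realises exactly the data model the pipeline assumes: control
metric values follow the linear age/sex normative model with additive
Gaussian residuals; sites add location offsets (per site × metric × region)
and multiplicative residual scale factors (per site × metric) — the ComBat
model family; TLE patients are displaced in designated regions by
`effect_size_w` residual SDs, either as an indicator set or shaped by
one-step diffusion from an epicenter seed (connectivity row normalised to
max 1), mirrored to the homologues for right-focus patients.

Functional targets are realised through vertex time series with three
controllable handles: a shared global component with per-region loading
(node strength), within-region vertex coherence (ReHo, via the
equicorrelated-Gaussian approximation W ≈ (1+(K−1)ρ_s)/K), and region
amplitude (SV, exact by linearity). Cross-region latent correlations follow
an exponential distance-decay template, giving maps realistic spatial
autocorrelation. The per-region global loadings are solved in closed form
(arcsine) with a short fixed point so expected node strength matches its
target; all temporal components are unit-variance AR(1) with lag-1
correlation 0.3. Because the computed metrics carry intrinsic sampling
noise on top of the configured residual SD, the displacement scale is
calibrated at run time by a small Monte-Carlo estimate of that intrinsic
SD, so `effect_size_w` is expressed in units of the *total* control
residual SD (a realized mean W displacement ≈ the configured value).

Default study conditions: two sites of 40 HC / 35 TLE / 6 FCD; ages uniform
on 18–60; T = 150 time points; 6 vertices per region; site offsets of 0.3
residual SDs and scale log-SD 0.15; 52% left-focus patients; FCD patients
carry no injected effect (a disease-control group). Metric baselines (SV 6,
ReHo 0.5, NS 0.3 per connected region, CT 2.8 mm, FA 0.45, MD 0.85) were
chosen so that targets stay far from the achievable-range boundaries of the
generative model (saturation would skew residuals) and the intrinsic noise
share stays well below the configured residual SD. Clinical covariates
(onset, duration, ASM count, FBTCS, Engel class, mean FD) are drawn with
realistic marginals but are *not* coupled to the imaging effects unless the
analysis constructs such coupling explicitly.

What the generator does not emulate — and hence what green tests cannot
certify about real data: biophysical BOLD dynamics and noise spectra, head
motion and scanner artifacts, non-Gaussian lifespan effects, genuinely
nonlinear structure–function relations, and lesion-driven signal dropout.
The synthetic connectome (distance-decaying edges plus a spanning tree for
connectedness) has realistic geometry but no true network topology of the
brain.

## Problem sizes and numerics

Desk-scale runs use a 20+6-region atlas; the atlas size is a constructor
parameter (a 360+14 configuration mirrors common full-scale use). Validation
runs size their cohorts to the property under test: 500 patients / 1000
controls for null-prevalence calibration (binomial SE ~1% per region), 60/60
for epicenter recovery and classification, 200 controls for normative
recovery, 200 replicates × 500 iterations for spin-test calibration. The
null-prevalence band check [0.03, 0.07] is intrinsically a ~2σ statement at
n = 500, so the test suite averages its in-band fraction over three
replicate cohorts rather than trusting a single draw.

Numerical conventions: midranks everywhere ranks are used; inclusive
thresholds; Cholesky-based Mahalanobis solves with explicit failure on
singular covariance (an error names the region); the spin assignment breaks
distance ties by index order; per-stage seeds derive from the master seed
and the stage name (CRC32), so partial reruns are reproducible; all
stochastic outputs are bit-identical under a fixed seed.

## Known limitations

ComBat assumes Gaussian batch effects and at least two subjects per batch;
no GAM or longitudinal variants. The normative model is linear in age. Spin
nulls require hemisphere-paired sphere coordinates and exclude midline
cortical parcels. Dominance analysis is exponential in predictors (capped at
10). The surgical-cavity overlap analysis expects a user-supplied
region-level overlap map; cavity segmentation is out of scope.
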