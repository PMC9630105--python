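# Methods

This note records the models implemented, the defaults chosen where the
underlying methodology left choices open, what the synthetic generators do
and do not emulate, and the numerical conventions that matter for
reproducing results.

## Calibration and summed probability distributions

A radiocarbon determination (age a, lab error σ) is calibrated against a
piecewise-linear curve (calendar grid θ, curve mean μ(θ), curve error
s(θ)): the posterior mass at θ is proportional to
N(a − μ(θ); σ² + s(θ)²), evaluated on a fixed 20-year calendar grid and
normalised to unit mass (conservation is asserted to 1e-9 in the tests).
Twenty years is used uniformly for calibration and SPD so all densities
share one grid resolution. Luminescence and U-series ages bypass the curve
and enter as calendar normals truncated at ±5σ. Dates whose 14C age comes
within 2σ of the curve's old limit trigger a warning: likelihoods there are
one-sided and medians unstable.

The quantile summary of a calibrated density (median, 95.4% range) is read
off the cumulative mass by linear interpolation. The normal-equivalent
sigma used downstream is (upper − lower)/4, i.e. the symmetric-normal
reading of a 95.4% (≈ ±2σ) range.

Same-level 14C dates are pooled before calibration by inverse-variance
weighting; the χ² statistic T = Σ wᵢ(aᵢ − ā)² with k − 1 df is attached and
a failure at α = 0.05 is reported (warning) without aborting, since
discrepant level pools are a data-quality signal, not a computational
error. Mixing methods (14C with TL/OSL/U-series) is refused; such a level
keeps one calibrated density per method and the assemblage density is their
unit-mass average, so every occupational unit contributes exactly once to
the SPD.

Eligibility filters for SPD and OLE: coefficient of variation ≥ 0.05
(inclusive at the boundary, exactly as the rule is stated), shell material
(marine reservoir offsets unknown in this period), and any
stratigraphic/cultural flag. Filtering is idempotent and order-independent;
every removal carries machine-readable reason codes.

SPD restricted to an analysis window truncates densities crossing the edge
without renormalising (logged via warning): renormalisation would silently
inflate the apparent occupation intensity of boundary assemblages.

## Optimal linear estimation

The boundary estimator is the classical Roberts–Solow optimal linear
estimator. On a working axis where the boundary lies beyond the maximum
sighting (cal BP is negated for end boundaries, used as-is for start
boundaries), with sightings x₁ ≥ … ≥ x_k:

- Weibull shape: v = (1/(k−1)) Σᵢ₌₂^{k−1} ln((x₁−x_k)/(x₁−xᵢ));
- weights: a = Λ⁻¹e / (eᵀΛ⁻¹e), with Λᵢⱼ = Γ(2v+i)Γ(v+j)/(Γ(v+i)Γ(j)) for
  j ≤ i (symmetric), evaluated via log-gamma;
- point estimate aᵀx; one-sided (1−α) bound x₁ + (x₁−x_k)/(S−1) with
  S = (−ln α / k)^(−v).

Minor published variants of this estimator exist (shape-estimate
denominator, bound constant); the variant above is pinned by a Monte-Carlo
coverage oracle: over 500 generator replicates with k = 10, the one-sided
95% bound must cover the planted boundary at a rate in [0.90, 0.99]
(measured ≈ 0.97). Records with all sightings identical, or with a
non-finite shape estimate, raise a degenerate-record error.

Date uncertainty is propagated by redrawing each sighting as
Normal(median, σ_equiv), re-sorting, and re-estimating; 10,000 iterations
by default. The reported boundary is the median of the iterations and the
95% interval their 2.5/97.5 percentiles; iterations that degenerate are
skipped, and only if more than half degenerate does the whole call fail.
Records of 5–10 terminal dates are the intended regime; three is the hard
minimum.

## Pollen transfer functions and delta correction

Weighted averaging: taxon optimum u_k = Σᵢ yᵢₖ xᵢ / Σᵢ yᵢₖ over training
samples; initial sample estimate Σₖ yᵢₖ u_k / Σₖ yᵢₖ. Averaging twice
shrinks the range, so an inverse (classical) deshrinking regression of
observed climate on initial estimates is applied; the deshrinking method is
switchable to none, since only "weighted averaging" itself is prescribed by
the methodology this follows. MAT and MAP are fitted independently. If the
initial estimates are constant (single effective taxon) the deshrinking
falls back to predicting the training mean.

Pollen filtering: assemblages under 100 counted grains are rejected;
non-terrestrial taxa are removed first, percentages renormalised, then taxa
under 5% are dropped and percentages renormalised again. The 5% rule is
applied per assemblage — the natural reading of a spectrum-level
exclusion — rather than dataset-wide.

Bootstrap cross-validation resamples training samples with replacement,
refits, and predicts the out-of-bag samples; r² (squared Pearson) and RMSE
are pooled over all out-of-bag predictions rather than averaged per cycle,
which is the stabler aggregate at 500 cycles. Cycles with no out-of-bag
samples are skipped and counted. Constant observed climate is reported as
r² = 0 with a degenerate flag.

Delta correction is additive for temperature,
T_sim(x,t) + (T_obs(x,0) − T_sim(x,0)), and multiplicative for
precipitation, P_sim(x,t) · P_obs(x,0)/P_sim(x,0). Both are exact for
constant (additive, resp. multiplicative) simulation bias — asserted as
property tests. Cells with simulated baseline precipitation ≤ ε (default
1e-9 mm) are masked rather than divided.

## Productivity dissimilarity and phase statistics

CORT is the correlation of first differences; constant series (zero
denominator) return 0 with a warning rather than NaN. dCORT multiplies the
Euclidean distance between raw value vectors by f(CORT) with
f(x) = 2/(1+exp(kx)). k = 2 by default, under which the behaviour
component accounts for (1 − f(1))·100 ≈ 76% of the index at maximal
positive correlation — the package computes this constant rather than
storing it; note "contribution" has no unique formal definition, and this
is the standard one. Series must share a time grid; no silent resampling
is performed.

Clustering is agglomerative with average linkage (UPGMA) — a robust
default for non-metric dissimilarities — cut at 3 clusters by default, both
configurable. Phase statistics classify each time point into a
stadial/interstadial phase (half-open on the younger edge so adjacent
phases partition time), and compare the two value sets with the two-sided
Wilcoxon rank-sum test (the Mann–Whitney U statistic is reported as W, as
R's `wilcox.test` does); an all-tied comparison is reported as W = n₁n₂/2,
p = 1 with a degenerate flag. CV is 100·sd/mean with the sample sd.

A default Greenland stadial/interstadial table (GI-14 through GS-5,
approximate event boundaries in kyr b2k, converted to BP by subtracting
0.05 kyr) ships as an in-code, user-replaceable default; a CSV phase table
is the primary ingestion path since event chronologies are revised.

NPP units: productivity appears in the literature both as g m⁻² yr⁻¹ and
(inconsistently, given the magnitudes involved) as kg km⁻² yr⁻¹. The
package does not adjudicate: `NPPSeries` and `AllometryModel` carry
declared unit strings, a single explicit constant (1 g m⁻² = 1000 kg km⁻²)
is exported, and nothing converts silently.

## Carrying capacity

The THB–NPP law is fitted on log10 scales with a two-stage robust linear
estimator: a Huber M-estimate provides starting values for a redescending
Tukey-biweight IRLS fit (statsmodels RLM). This pairing approximates an
MM-type estimator with the tooling available in the scientific Python
stack; its behaviour is pinned by tests — planted coefficients are
recovered within the fit's own 95% CI in ≥ 90 of 100 replicates, and under
10% gross outliers the robust slope deviates from truth less than ordinary
least squares does. Datasets that are tiny (< 4 points) or exactly
collinear fall back to least squares. Prediction intervals use the
parameter covariance plus residual scale on the log10 axis with a normal
quantile.

Damuth partitioning: D_i = c·W^(−3/4), c = THB/ΣW^(1/4), B_i = c·W^(1/4).
Closure Σ B_i = THB holds algebraically, and is asserted at 1e-9 relative
on 1,000 random communities; the log-log slopes of D and B against W are
asserted at −0.75 and 0.25 to 1e-9. Size classes use half-open intervals:
small < 10 kg, medium [10, 100), medium–large [100, 500), large ≥ 500 kg
(the printed "10–100"-style ranges are ambiguous at their endpoints; the
boundary mass goes to the heavier class).

Validation against modern density compilations pairs observed and
predicted densities by taxon and correlates them on log10 scales (the
relations are log-linear; switchable to linear). Sites with fewer than 3
usable species are skipped and reported.

Minimum census: per region, a species' chronological range runs from the
oldest upper bound to the youngest lower bound over its dated occurrences
(a single occurrence contributes its own 95.4% interval), and the species
joins every phase its range overlaps. Rarefaction interpolates richness by
the sample-based hypergeometric formula (exact integer binomials; equal to
the exhaustive-subset average, asserted for all matrices up to 8 LFAs) and
extrapolates with the standard incidence-based Chao2-type asymptotic
estimator; the 95% CI comes from a seeded bootstrap over LFAs (500 draws).

## Synthetic generators: what they emulate, and what not

- Dates: uniform occupation between two boundaries — the simplest process
  consistent with OLE's stationary-record assumption — mapped through a
  smooth synthetic calibration curve (monotone, wiggle amplitude and error
  loosely modelled on glacial-period curves) with normal lab error drawn
  from 150–400 yr, realistic for 40-kyr-old samples. Defaults: occupation
  48,000–40,000 cal BP, 30 levels, 2 dates per level. Shell, flagged and
  high-CV dates are injected at configurable rates for filter bookkeeping
  tests. Not emulated: research-intensity and taphonomic loss gradients,
  curve plateaus, inter-site dependence — so SPD shape tests here say
  nothing about those biases in real data.
- NPP: three region profiles with distinct stadial/interstadial level
  means (defaults 0.271/0.339, 0.300/0.312, 0.259/0.258 in display units,
  i.e. the contrast structure the clustering must separate) plus i.i.d.
  Gaussian noise (sd 0.01) on a shared 0.2-kyr grid, 8 sites per profile.
  Not emulated: autocorrelated climate noise, within-region heterogeneity,
  ecotones; recovery ARI ≥ 0.9 over 20 seeds shows separability under the
  planted contrast, not clustering power on arbitrary real series.
- Pollen: unimodal Gaussian responses (tolerance 3 °C) of 12 taxa over a
  −5…15 °C MAT gradient, MAP varying in step, multinomial counts at depth
  400 (None = noise-free proportions). Edge-of-gradient taxa have
  truncated responses, so their optima are biased inward — recovery tests
  check interior taxa. Not emulated: uneven taxonomic resolution,
  long-distance transport, no-analogue fossil spectra.
- Modern densities: NPP log-uniform over 50–2000 g m⁻² yr⁻¹; THB from the
  planted law (slope 1.401, intercept −0.642) with lognormal scatter
  (0.10 in log10); 3–15 species per site with log-uniform masses
  1–1000 kg; densities are the exact Damuth partition times lognormal
  noise (0.10). 516 sites by default, matching the scale of modern
  protected-area compilations.

Every generator is deterministic given (scenario, seed) and scenarios
round-trip through plain-dict serialization.

## Pipeline and reproducibility

The `run_all` orchestration reads a YAML config (paths, parameters, unit
declarations), validates all paths before any stage runs, executes
filtering → calibration/combination → SPD and OLE per culture × region →
clustering and phase statistics → THB fit, validation and per-phase
carrying capacity, and writes a manifest with every parameter, seed,
per-stage row counts and the SHA-256 of every output. Reruns under the same
config and seeds are bit-identical (asserted). Exit codes distinguish
config, data and numerical failures.

Default problem sizes in the test and acceptance runs (500 coverage
replicates, 20 clustering seeds, 100 CI-calibration replicates at n = 200,
2,000–10,000 OLE iterations, 60–100 bootstrap cycles where full 500-cycle
runs add nothing to the assertion) were chosen so the whole suite completes
in well under a minute on one core while keeping every Monte-Carlo
assertion's sampling error far from its acceptance band.

## Known limitations

- OLE assumes the record continues to a sharp boundary with stationary
  sighting intensity; rapid abandonment or strongly pulsed occupation
  violates it, and the resampling interval reflects date uncertainty only,
  not model misspecification.
- SPD is used as an occupation-frequency summary, not a demographic proxy.
- The WA implementation deliberately omits WA-PLS and analogue methods;
  with strongly truncated responses at gradient ends, optima are biased
  inward (inherent to WA).
- The carrying-capacity model yields potential (carrying-capacity)
  biomass, not realized abundance: predation, migration and megafaunal
  grazing efficiency are out of model.
- Bayesian age modelling with outlier handling is intentionally out of
  scope; boundary tables produced here contain only the OLE columns.
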