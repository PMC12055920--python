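# Methods

## Model and procedure

`rptlab` quantifies non-operant ("liking") judgment from 7-point Likert
picture ratings using relative preference theory (RPT). Each participant
rates 8 pictures in each of 6 affective categories on −3..+3. Per
participant, category and valence, three variables are computed:

- **K** — mean rating intensity. The ratings are half-wave rectified into
  an approach part (positives) and an avoidance part (negatives), and K is
  the sum of one part divided by the number of pictures in the category
  (N = 8, zeros included). Approach K ∈ [0, 3], avoidance K ∈ [−3, 0].
- **σ** — sample standard deviation (N−1 denominator) of the same
  rectified N-vector.
- **H** — Shannon entropy (bits) of the rating pattern: proportions
  p_i = a_i / Σ a_j over rating magnitudes, H = Σ p_i log2(1/p_i), with
  0·log(1/0) = 0 and H ≡ 0 for an all-neutral category (K = 0), where the
  proportions are undefined.

Three curve families relate these variables, fitted at individual and
group (pooled participant × category) level:

- **Value function (K, H)** — logarithmic `H = a·log10 K + b` and
  power-law `H = b·K^a`, both via simple linear regression after log10
  transformation of K (and of H for the power law). Exponents 0 < a < 1
  flag scale-invariant (asymptotic) behavior.
- **Limit function (K, σ)** — quadratic `σ = aK² + bK + c`; concave
  (a < 0) fits are the admissible, Markowitz-like mean–variance shape.
- **Trade-off function (H−, H+)** — radial: the mean distance
  r = mean √(H−² + H+²) of a participant's category points from the origin.

Avoidance-side fitting is done on magnitudes |K−| so the logarithms are
defined and the quadratic vertex lies at positive K; only the negative
offset β− is re-signed on output.

### Admissibility screening

Individual fits are screened rather than constrained: a fit is admissible
when (i) it used ≥ 3 points with a computable R², (ii) optionally no point
lies beyond 3×IQR of the fitted y-values, and (iii) its curve direction
(slope sign, or curvature sign for quadratics) agrees with the pooled
group fit. Inadmissible fits propagate as missing features, mirroring how
exclusion — not constrained optimization — handles convergence
pathologies.

### The 15 features

From the value fits: loss aversion LA = |a−/a+| (power-law exponent
ratio), risk aversion RA = |H″/H′| of the approach curve at K = 1.5, loss
resilience LR (same form on the avoidance curve), and the offsets
β± = ±10^(−b/a) from the logarithmic fits. RA/LR are computed from the
power-law family: for the logarithmic family |H″/H′| = 1/K identically,
which carries no individual information; the power-law closed form
(1−a)/K does. A logarithmic variant remains available via `ra_family`.

From the quadratic fits: turning point ρ = −b/(2a), apex α = c − b²/(4a),
and quadratic area q = ∫σ dK over {K ≥ 0, σ ≥ 0} (from max(0, lower root)
to the upper root; 0 if the parabola never rises above the K-axis).

From the trade-off points: mean polar angle θ (atan2(H+, H−), degrees;
45° = balanced, > 45° = approach-weighted) with SD σθ, and mean radius r
with SD σr. Origin points have radius 0 but no angle; they enter the
radial statistics and are excluded (and counted) from the angle
statistics. A single usable point has SD 0 by convention so downstream
summaries stay numeric.

### Screening and outlier policies

Participant screening: straightlining (identical response across a
section; the rating block when no section labels exist), ≥ 10 diagnosed
illnesses, minimal rating variance (max − min ≤ 1 across all 48 ratings),
and education mismatch combined with completion below 500 s (800 s for
large-cohort runs). The education level→years mapping is a configurable
band table (e.g. bachelor → 16–17 years), since no canonical mapping
exists. Criteria that need absent metadata evaluate to "not evaluable"
and never exclude. Screening is idempotent.

Feature-level outliers: either a per-feature 3×IQR fence or fixed
thresholds (LA > 200, q+ > 100) for the two features with rare extreme
values; the two modes are mutually exclusive by design and both
switchable off.

### Cohort statistics

Per cohort and feature: mean, sample SD, SEM, t-based 95% CI (the
conservative standard at these n), median and IQR. Across cohorts:
tie-corrected Kruskal–Wallis H (χ², k−1 df; valid with ≥ 5 observations
per group), Dunn's pairwise z-tests on pooled ranks with tie correction,
two-sided, Holm-corrected across the pairs, and pairwise two-sample
two-sided Kolmogorov–Smirnov tests. Dunn's test is implemented directly
(no dedicated post-hoc package is used) and validated against a
brute-force rank oracle. Age effects: univariate OLS of each feature on
z-scored ordinal age (band midpoints: 18–24→21, …, 65+→70; configurable),
reporting the slope per SD of age as the standardized β, adjusted R², and
the overall-regression p flagged at the Bonferroni level 0.05/15 ≈ 0.0033.

## Synthetic cohorts

The generator emulates the study design (6 categories × 8 pictures,
−3..+3 scale) with a discretized clamped Gaussian: participant shift
δ_p ~ N(0, 0.5), category latent means μ_c = (−2.2, −1.2, −0.4, 0.4, 1.2,
2.2) spanning the valence axis, per-picture rating
clip(round(N(μ_c + δ_p, τ_c)), −3, 3) with τ_c = 1. The dispersion and
shift defaults were fixed once, at design time, as the smallest-structure
model that yields graded bivalent data with both valences populated in
most participant × category cells; with them, pooled group fits emerge
concave and scale-invariant (power-law exponent ≈ 0.45–0.47, quadratic
curvature < 0, R² ≈ 0.83–0.87 at n = 200) without any tuning toward those
properties. Ages are drawn from ordinal bands with an optional
exponential right-skew parameter for testing age regressions.

What the generator does *not* emulate: real picture-set norms, response
styles (acquiescence, category-order effects), within-category
heterogeneity of picture valence, or response times. Passing tests on
synthetic cohorts therefore demonstrate that the pipeline recovers the
qualitative lawful structure from data of the assumed form — not that
real cohorts have that structure.

Exact mirror symmetry (negating all ratings swaps approach and avoidance
summaries, with K negated) is a property of the analysis and is tested by
negating generated records; negating the latent μ_c alone mirrors the
rating distribution only in distribution, because the seeded Gaussian
draws cannot be sign-coupled to μ, and is tested statistically.

## Numerical choices

- Fitting logarithms are base 10; entropy is base 2 (bits).
- Goodness of fit is computed in the regression (transformed) space;
  adjusted R² uses n − p − 1 with p the coefficient count excluding the
  intercept; F is the standard overall-regression statistic.
- SST = 0 (all y equal) defines R² = 1 if residuals also vanish, else 0,
  and marks the fit degenerate; the thresholds are relative to the data
  scale (machine epsilon based).
- Boundary envelopes translate the fitted curve along y (in the family's
  natural space — multiplicatively in the prefactor for power laws) by
  the 95th percentile of signed residuals, with linear-interpolation
  quantiles; containment is recounted from the translated curve and is
  ≥ 95% by construction. The translation construction is a design choice:
  only the containment property, not an algorithm, is prescribed by the
  envelope concept.
- Quantities reported per participant stay NaN (never imputed) when the
  fits they need are inadmissible.

## Problem sizes

Default test and verification runs use synthetic cohorts of 50–200
participants, 500-replicate null calibrations and 10⁴-vector entropy
oracle sweeps — sizes at which every reported property is stable under
seed changes while the full suite runs in seconds.

## Known limitations

- The K denominator (all N pictures, zeros included) is a reasoned
  convention; the nonzero-only alternative is available via
  `denominator="nonzero"` for sensitivity analysis and changes the K
  scale (forces |K| ≥ 1).
- Individual fits rest on ≤ 6 points per valence; their R² is accordingly
  optimistic, which is why admissibility screening, not model selection,
  gates the features.
- Cross-cohort comparisons of unit-bearing features (offsets, apices,
  turning points, areas) are labelled but not suppressed; only the seven
  dimensionless features are flagged as directly comparable.
- No covariate-adjusted (multivariable) demographic modeling; age is the
  single probed covariate.
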