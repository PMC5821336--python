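# Methods

This note documents the statistical procedures implemented in `condclim`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Body condition

Condition is the residual of a per-species ordinary least-squares
regression of body mass (g) on wing length (mm), pooled across sites,
years, ages and sexes. Pooling is the simplest defensible reading for a
structural-size correction; a per-site regression would absorb genuine
site differences in condition into the size correction. Species with
fewer than three distinct wing lengths are rejected (the fit is singular
or saturated). A per-species regression of wing length on year is
available as a drift diagnostic (`wing_trend`): a secular change in wing
length would contaminate the condition index.

## Climate windows

Candidate windows are inclusive day ranges `(start, end)` counted
backwards from 15 August (offset 1 = 14 August), `1 ≤ end ≤ start ≤ 365`,
optionally on a stride grid. The aggregation statistic is the arithmetic
mean of daily values; sums and extremes are out of scope. Aggregates are
computed per site-year from the site's nearest weather station and
centred on their grand mean over all site-years (equal weight per
site-year). Centring commutes with aggregation, so the slope and
curvature coefficients are invariant to adding a constant to the daily
series — asserted in tests.

The baseline model contains an intercept, age class, sex (three levels,
"unknown" kept as a level), time of day and its square, and day of season
and its square. Each candidate is fitted twice, with a linear and with a
quadratic climate term, and AICc (`−2logL + 2k + 2k(k+1)/(n−k−1)`, k
counting the residual variance) selects among all (window, shape) pairs.
Ties break deterministically: smaller AICc, then shorter window, then
more recent end, then the linear shape.

**Fitting engines.** The scan's default engine solves every candidate by
OLS via Frisch–Waugh residualization: the baseline is projected out of
the response and of all window aggregates at once, leaving per-window
1×1 or 2×2 normal equations that are vectorized across the full
candidate set. This is exact, agrees with an independent per-candidate
least-squares loop to 1e−10 (tested), and is identical to the mixed
model when no individual is recaptured. A per-candidate linear mixed
model with an individual random intercept (statsmodels MixedLM, ML) is
available (`method="mixed"`) and is the faithful choice for
recapture-heavy data; it is orders of magnitude slower, so the pipeline
default is the OLS engine, with mixed-model fits recommended for final
coefficient estimates when recapture rates are high.

**Randomization test.** The false-positive guard permutes the
year→climate mapping (condition data, and hence all seasonal covariates,
untouched), re-runs the entire scan per permutation and computes
`p = (1 + #{permuted ΔAICc ≥ observed}) / (n_rand + 1)` with
ΔAICc = AICc(null) − AICc(best). The permutation is over whole years, so
within-year autocorrelation is preserved. A variable "has a signal" when
`p < α` (default 0.05) — note `n_rand = 19` makes the smallest attainable
p exactly 0.05, so at least 20 permutations are needed at α = 0.05.
Requires ≥ 3 distinct years. Simulations show the empirical type-I rate
is consistent with α and that a planted window with an effect 3× the
residual SD (aggregate scale) is relocated with Jaccard overlap ≥ 0.6
essentially always at stride 5.

## Multi-climate model

Variables passing the randomization screen are combined. Their window
aggregates are grouped by transitive closure of pairwise Pearson
|r| > 0.6, and every subset of groups is fitted on top of the baseline
(shapes frozen from the scan; at most 6 groups). Exclusion rules:

- *not-in-top-set*: absent from every model within ΔAICc ≤ 2 of the best;
- *hitchhiker*: the best top-set model containing the variable improves
  the log-likelihood by < 1.0 over the best top-set model without it,
  **and** its averaged 95% CI spans zero (both coefficients).

The hitchhiker rule is an operationalization of the standard
uninformative-parameter idea; both thresholds are configurable.
Coefficients of the survivors are full (zero-substituted) Akaike-weight
averages over the ΔAICc ≤ 2 set, with unconditional covariance
`Σ w_m (Σ_m + (β_m − β̄)(β_m − β̄)ᵀ)`. Full rather than conditional
averaging is used because absent-from-model coefficients still feed the
site-level projections downstream. Site-specific slopes come from
refitting the retained subsets with fixed site × climate (and
site × climate²) interactions — site main effects are added so slope
differences are not confounded with site intercepts — and averaging the
same way. Sites with a single year of data are dropped from the
interaction fit.

## Sensitivity and projection

Sensitivity is the tangent of the fitted response at mean climate:
`s = β₁ + 2β₂C̄`, `Var(s) = Var(β₁) + 4C̄²Var(β₂) + 4C̄Cov(β₁,β₂)`.
Because fits centre climate on its grand mean, the tangent at the mean is
evaluated at C̄ = 0 (so `s = β₁`); the general form supports tangents at
other climate values. Gram-scale sensitivities divide by the species'
observed mean mass (mean over all captured individuals) × 100 to give
%/unit. Sites whose observed years all lie strictly on one side of the
grand-mean climate are excluded per variable (no extrapolation to the
mean); a year exactly at the mean keeps the site.

Projection to 2050 multiplies each percent-scale sensitivity by its
season-matched exposure and sums: `dB/dT = Σᵢ sᵢ·eᵢ`. A window's seasons
are the meteorological seasons (DJF/MAM/JJA/SON) of the months its day
range covers in a non-leap reference year; multi-season windows get the
unweighted mean of the seasons' projected changes (day-weighted averaging
would be a defensible alternative; unweighted is used). Wind carries a
single annual exposure; sunshine has none and contributes zero with a
warning. Exposure is treated as error-free and identical across sites,
so the projection SE is `sqrt(Σ (eᵢ·SEᵢ)²)`.

## Species signal

Site-level sensitivity estimates are decomposed by a weighted one-way
random-intercept model `y = μ + a_species + e`, `a ~ N(0, σ²ₛₚ)`,
`e_i ~ N(0, σ²ₚₒₚ/w_i)`, fitted by REML written in-package: the
likelihood is profiled down to a one-dimensional search over the variance
ratio using Sherman–Morrison per-group inversions, with the zero-variance
boundary checked explicitly (components are clamped at 0). The fit
matches lme4 on weighted unbalanced data to six digits and the
closed-form one-way ANOVA estimator exactly in the balanced equal-weight
case (tested). Weights default to 1/SE — the literal published scheme —
with 1/SE² ("inverse-variance") and unweighted as switches; weights are
normalized to mean 1, a pure reparameterization that makes σ²ₚₒₚ the
average per-observation residual variance and the ratio invariant to
rescaling the data. The ratio `σ²ₛₚ/(σ²ₛₚ+σ²ₚₒₚ)` is the intraclass
correlation; the same machinery runs on projections.

Because the decomposition consumes *estimated* sensitivities, sampling
error inflates the population component. Two mitigations are
implemented: the inverse-SE weighting, and a diagnostic quadratic
regression of each site's absolute deviation from its species mean on
the number of years sampled, reported as AICc(null) − AICc(quadratic)
(positive values support a sampling-variance effect).

Species observed at fewer than `min_sites` sites (default 7) are removed
from pooled analyses before the decomposition.

## Traits, phylogeny, geography

Each trait hypothesis is a weighted regression of estimates on one trait
compared by AICc (ML) to an intercept-only null on identical rows and
weights: weighted least squares at species level, the weighted
random-intercept model (species as the grouping factor) at site level.
ΔAICc < 0 favours the trait. Phylogenetic distance is half the patristic
tip-to-tip distance on an ultrametric tree (divergence time, Myr;
dendropy). Geographic distance is great-circle (haversine) — at the
≤ 300 km scale of a national scheme it differs from planar Euclidean
distance by < 0.5%. Dissimilarity (|sᵢ − sⱼ|) is regressed on distance by
OLS, flagging "significant-positive" when the slope is positive with a
95% CI excluding zero. These pairwise regressions deliberately ignore
pair non-independence (matching the published procedure); a Mantel-style
permutation p is computed alongside as a clearly-labelled diagnostic.
Concordance of affected-variable sets (whether two species share signal
status for a variable) is related to divergence time by logistic
regression, with complete separation detected and reported rather than
fitted.

## Synthetic data

The generator emulates a national CES scheme: sites on a small
coastal-plain grid matched to their nearest station, 12 evenly spaced
visits per season (12 April–14 August), at least one bird per species per
visit (1 + Poisson extras), recaptures of ringed individuals at a
configurable rate (default 0.2), and daily climate per station as a
seasonal sinusoid + per-year anomaly + AR(1) noise + demeaned station
offset, clipped to physical ranges. Default climate parameters are
temperate-maritime (annual mean 10 °C, seasonal amplitude 7.5 °C, late
July peak; humidity ~81%, etc.). Mass combines a species baseline, wing
allometry (0.25 g/mm), the planted climate effects, covariate effects,
an individual random intercept (SD 0.3 g) and residual noise (SD 0.8 g)
— all chosen as plausible passerine magnitudes.

Planted climate effects act on the window aggregate centred at its grand
mean over site-years, so the planted β₁ *is* the gram-scale
tangent-at-mean and recovery can be scored directly. The realized linear
slope varies by species and by site within species with configurable
SDs; their squared ratio sets the true intraclass correlation. Percent
scaling divides by species mass, so identical gram-scale slopes across
species of different sizes still produce a genuine percent-scale species
signal — a feature to keep in mind when reading the fixture's variance
ratios.

What the generator does **not** emulate: effort variation, trap shyness,
observation error in mass/wing beyond rounding, migration phenology
(all species are present all season), spatially structured climate
effects, and non-Gaussian residuals. Passing tests therefore demonstrate
the statistical machinery recovers known truth under the stated
generative model, not that real CES data meet those assumptions.

## Problem sizes and numerical choices

The test suite and acceptance script run simulations at deliberately
compact sizes chosen as the smallest designs at which each property is
statistically decidable: window recovery at 1 species × 6 sites ×
15 years (stride 5, 20 permutations), the type-I check at 50 null
replicates, ICC recovery at 20 species × 8 sites × 50 replicates per
planted ratio, and the end-to-end fixture at 5 species × 6 sites ×
10 years with ~1.3 captures per species-visit. The fixture's planted
temperature effect is −0.3 g/°C over days 100→40 (species SD 0.04,
site SD 0.1) plus a weaker humidity effect — strong enough that most
species pass the 20-permutation screen at these sample sizes.

Numerical details: Gaussian ML log-likelihoods from residual sums of
squares; near-zero residualized climate variance (threshold 1e−12·n)
treated as "no information" (slope 0, null RSS), which makes the
constant-climate scan resolve to the most recent single day by
tie-break; the REML search runs over log variance ratio in [−14, 14]
with the boundary checked; station-matching distances rounded to 1e−6 km
so exact geographic ties break lexicographically; negative variance
components clamped to zero and logged.

## Known limitations

- The best-window search induces a winner's-curse: selected windows have
  mildly inflated |β| even after the randomization screen. The fixture's
  recovered sensitivities show this as a small upward bias in magnitude.
- The scan's OLS engine ignores the individual random intercept during
  *selection* when recaptures exist (the mixed engine is available but
  slow); with the default ~20% recapture rate the induced dependence is
  modest and affects SEs more than point estimates.
- Model averaging is restricted to the ΔAICc ≤ 2 set; averaging over all
  models with Akaike weights is a defensible alternative.
- Pairwise distance regressions inherit the pseudo-replication of the
  published procedure; use the Mantel diagnostic for honest inference.
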