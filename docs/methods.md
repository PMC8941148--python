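# Methods

This note documents the models, numerical choices and calibration
behind `aapflux`, and what the synthetic-data tests do and do not show
about real field data.

## Rate derivation

**Winkler O₂.** Dissolved O₂ follows the iodometric stoichiometry
1 mol O₂ ≡ 4 mol thiosulfate; thiosulfate is standardised against KIO₃
(1 mol IO₃⁻ ≡ 6 mol S₂O₃²⁻). The effective sample volume subtracts the
2.4 mL of fixing reagents (2 × 1.2 mL MnCl₂ and NaI/NaOH) from the
nominal 115 mL bottle, the standard displacement correction; it can be
switched off (`apply_displacement_correction=False`) for comparison
with uncorrected workflows. Respiration is
(mean T₀ − mean end)/h over a 24 h incubation; NPP is the sign-flipped
difference for white-light bottles. Replicate end bottles are kept as
individual observations against the T₀ mean so the mixed model sees the
true replicate structure. Negative respiration (O₂ increase in the
dark) is retained with a warning: truncation would bias the treatment
contrast. Per-date 95 % CIs use a Welch t interval on the difference of
bottle means (the uncertainty statement is not prescribed by the field
protocol; Welch is the conservative default for small unequal-variance
samples).

**Carbonate system.** Gran alkalinity regresses F(Vₐ) = (V₀+Vₐ)·10^(−pH)
on the points with pH < 4.5 (configurable); the x-intercept is the
equivalence volume and TA = Vₑ·Cₐ/V₀. The forward titration simulator
solves the full charge balance of a NaHCO₃-type solution by Brent's
method at each acid addition and, by construction, has exactly known
alkalinity; titrating to pH ≈ 3 (as in practice) keeps the residual
carbonate bias of the Gran line below ~0.5 % across TA 0.2–4 mmol L⁻¹.
Dissociation constants are zero-ionic-strength freshwater fits (Plummer
& Busenberg-type K₁/K₂, Harned & Owen-type K_w) on the molar scale —
appropriate for a dilute oligotrophic lake, so no ionic-strength
corrections; pH is treated as free-proton scale. DIC follows from
CA = TA − [OH⁻] + [H⁺] and
DIC = CA·(1 + h/K₁ + K₂/h)/(1 + 2K₂/h).

**Radiotracers.** Specific activity converts as 1 GBq mmol⁻¹ =
6·10⁴ DPM nmol⁻¹. Monomer rates are (sample − killed) DPM divided by
(DPM nmol⁻¹ × incubated volume × hours); the molar rate is multiplied
by the substrate's carbons per molecule (glucose 6, pyruvate 3, leucine
6, thymidine 10) to report nmol C L⁻¹ h⁻¹. Whether published
"nmol C" values for such assays include this factor is ambiguous in
general, so `carbon_units=False` reports substrate-molar rates instead.
Killed-control excess below zero is floored at 0 with a warning
(counting noise can invert small signals). Fractionated bicarbonate
incorporation normalises each counted fraction by its filtered volume
(30 mL onto 2.5 µm, 5 mL refiltered onto 0.17 µm, 5 mL filtrate; total
activity from a 1 mL aliquot), takes the incorporated fraction of the
added label relative to the per-litre total activity, and multiplies by
DIC over the incubation time; the total rate is the sum over fractions
and a summed fraction > 1 raises a mass-balance error.

## Light-effect model

Rates are analysed untransformed with a random intercept per sampling
date. The ML fit profiles the likelihood over λ = σ_d²/σ²: for fixed λ
the GLS coefficients and σ̂² are closed-form (group-wise Sherman–
Morrison inversion of I + λZZ′), leaving a bounded one-dimensional
search on log λ with an explicit λ = 0 boundary check. The residual
variance is floored at 10⁻²⁴ of the response scale so exactly-fitting
(noise-free) data degrade gracefully instead of producing a likelihood
singularity. REML is available but ML is the default, matching the
`nlme::lme(method="ML")` workflow this reimplements; the profiled fit
agrees with `statsmodels` MixedLM (ML) to ~10⁻⁶ in the test suite.
One-observation-per-group designs are rejected: σ_d² and σ² are then
confounded and any split would be arbitrary.

Treatment significance is a likelihood-ratio test against the model
without the treatment term, referred to χ² with df = 1 ("ANOVA" in the
mixed-model sense); an F variant with containment denominator df is
provided for sensitivity. The headline summary is
percent = 100·|β₁|/μ_dark, where μ_dark is the model-implied mean under
the dark (reference) treatment, with CI endpoints scaling β₁'s Wald
interval by μ_dark. A delta-method CI was evaluated and rejected as the
default: under a multiplicative truth the estimates of β₁ and μ_dark
are positively correlated, and adding Var(μ̂) without that covariance
widens the interval and overcovers.

Covariate models log₁₀-transform environmental variables (raising on
non-positive values unless flagged pre-transformed) and test light ×
covariate interactions by the same LRT; per-treatment intercepts and
slopes are linear combinations of the fixed effects with delta SEs.

## Seasonal budget

Photoperiod uses the standard solar declination/hour-angle daylength at
sun altitude −0.833°, accurate to ~0.2 h at temperate latitudes;
measured sunrise/sunset times can be supplied as data and override the
formula. Daily rates weight the hourly measurements by daylight hours
L: NPP acts for L hours, dark respiration 24 h, and the IR scenario
applies the IR rate during daylight and the dark rate at night. Daily
values are linearly interpolated between sampling dates, constant-
extended to the window edges, and trapezoid-integrated on a daily grid
over a season of 180 days (the period with water temperature > 10 °C)
starting at the first qualifying date; a left-step interpolation is
available as a sensitivity alternative since the integration rule
between sparse sampling dates is a genuine modelling choice.
Conversion to g CO₂ multiplies by RQ (default 1 mol CO₂ per mol O₂;
exposed because freshwater respiratory quotients vary), the molar mass
44.01 g mol⁻¹, and the layer volume (1.16 km² × 0.5 m = 5.8·10⁸ L).
NPP is common to both scenarios and cancels exactly in the dark−IR
difference.

## Community model

Rare ASVs are removed unless their count exceeds 3 in at least 20 % of
samples (strict inequality; the filter is idempotent). The variance-
stabilising transform is an independent re-derivation of the common-
dispersion negative-binomial case: median-of-ratios size factors,
pooled method-of-moments dispersion α on normalised counts, and the
closed-form integral of 1/√(q + αq²),
f(q) = log₂((1 + 2αq + 2√(αq(1+αq)))/(4α)), which is log₂-like at
large counts. It is a re-derivation, not a bit-exact clone of any
reference implementation, so community results are validated by
properties (variance flatness across a 10-fold mean gradient,
monotonicity), not by digit matching. Under-dispersed inputs fall back
to log₂(q+1) with a warning. Negative transformed values are clipped
to zero before Bray–Curtis (which requires non-negativity), with a
warning.

DistLM Gower-centres the squared dissimilarities,
G = −½J(D∘D)J, and tests predictors through
pseudo-F = [tr(HGH)/m]/[tr((I−H)G(I−H))/(n−m−1)] with H the hat matrix
of the centred, standardised predictors. Marginal tests permute sample
labels freely; sequential tests use Freedman–Lane residual permutation
under the reduced model — the permutation scheme of the commercial
implementation this emulates is undocumented, so the conventional
choices are used and stated. When n! does not exceed the requested
permutation count the null is enumerated exhaustively and the p value
is exact; otherwise p = (hits+1)/(draws+1). Forward selection maximises
adjusted R² (a distance-based AIC is the alternative). dbRDA is the
eigendecomposition of HGH with scores scaled by √eigenvalue and
predictor arrows as correlations with the axis scores; with Euclidean
input distances it reduces to classical redundancy analysis, which the
tests verify against an SVD oracle.

## Synthetic-data generator

The generator emulates the field design: roughly monthly sampling
April–November over two years (16 dates), triplicate bottles per
treatment, a sinusoidal seasonal temperature track, and multiplicative
treatment effects on a date-varying baseline,
y_ij = (μ₀ + b_j)(1 + effect) + ε_ij. Defaults are the study
conditions: −15.2 % IR effect on respiration; +18.1 %, +9.5 %, +5.9 %
on glucose, pyruvate, leucine; 0 for thymidine and bicarbonate (both
reported non-significant); dark means 0.30 µmol O₂ L⁻¹ h⁻¹
(respiration), 0.55/12.67/0.36/0.12 nmol C L⁻¹ h⁻¹ (glucose/pyruvate/
leucine/thymidine), CO₂ fixation ~5-fold below respiration. The
between-date (0.08) and residual (0.02 µmol O₂ L⁻¹ h⁻¹) SDs are
calibration choices — the study reports only treatment contrasts, not
variance components — set so that replicate scatter and date-to-date
variation resemble the published per-date error bars; other analytes
share these as coefficients of variation, with the residual SD constant
per analyte as the model assumes. Titration volumes are back-computed
through the exact Winkler stoichiometry and perturbed with 0.002 mL
burette noise; DPM are Poisson-distributed around their expectation
when counting error is on. Configurations in which negative rates or
titrant volumes have > 1 % probability are rejected as unusable.
Community counts are Dirichlet-multinomial with log-linear covariate
effects on the composition and always include a null covariate for
type-I checks.

What the generator does *not* emulate: within-day rate variation,
quench/counting-efficiency drift, isotope dilution by ambient substrate
pools, Winkler interferences (nitrite, iodine volatilisation),
taxonomic structure or phylogenetic correlation in the count table, and
temporal autocorrelation beyond the date random effect. Passing
recovery tests therefore demonstrates correctness of the computations
and calibration of the inference under the stated model, not robustness
to those field realities.

## Problem sizes used in checks

Recovery checks simulate 400 replicate campaigns of 16 dates × 3
replicates and require |bias| < 1.5 percentage points with 92–98 % CI
coverage per analyte; type-I checks use 1000 (mixed model) and 200
(DistLM, community) null replicates; permutation enumeration is exact
at n = 5. The acceptance script averages 60 replicate campaigns per
seed, a compromise keeping the Monte-Carlo error of the reported
percent effects near half a percentage point.

## Known limitations

- Percent-effect CIs condition on the estimated variance ratio (Wald);
  with 16 dates they are mildly anti-conservative for β but mildly
  conservative for the percent ratio (see above), both within the
  tested coverage band.
- The Gran estimate carries a ~0.2–0.5 % low bias from residual
  carbonate buffering in the pH < 4.5 window; it propagates only into
  bicarbonate-incorporation rates and cancels in dark-vs-IR contrasts.
- DistLM p values are seed-reproducible but permutation-stream
  dependent when sampled rather than enumerated.
- The budget treats the 0.5 m surface layer as homogeneous and ignores
  gas exchange, deeper respiration and sediment terms by design.
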