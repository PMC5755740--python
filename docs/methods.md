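# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `phenorisk`.  It is written for users who need to judge
what the package's outputs do and do not mean.

## Thermal response functions

Every process is a named parametric form (`phenorisk.forms.FORM_PARAMS`)
evaluated in `phenorisk.thermal`:

| process | form(s) | parameters | notes |
|---|---|---|---|
| development rate | Brière-1 | a, Tmin, Tmax (°C) | clamped to 0 outside (Tmin, Tmax); never negative |
| development-time spread | logit on ln(time) | intercepts a_i, common slope b | median at temperature i is exp(−a_i/b) |
| immature mortality | exp-quadratic | b1, b2, b3 | proportion scale, clipped to [0, 1] |
| adult senescence | exponential / Stinner | b1, b2 / C1, C2, k1, k2, T0 | rate per day; longevity = 1/rate |
| lifetime fecundity | exp-polynomial / Gaussian | b1..b3 / y0, a, b, x0 | Gaussian floored at 0 (a strongly negative baseline makes only the peak region meaningful) |
| cumulative oviposition | cubic-exponential / logistic / gamma CDF | — | argument is normalized female age x = age / mean survival time |
| life-table parameter vs T | quadratic | a, b, c | fitted to simulated life-table output |

Choices worth flagging:

- The Brière-1 radical is included even though informal renderings of the
  model sometimes drop it; the closed-form optimum used here is the
  Brière-1 one and agrees with brute-force maximization to < 0.01 °C.
- Mortality parameters are interpreted on the **proportion** scale.  Some
  published parameter sets for these species are internally inconsistent
  on any scale (one pupal set has an obviously garbled curvature term);
  the packaged `rosa_like` / `quilicii_like` fixtures archive the printed
  values verbatim and say so in their headers, while the fully synthetic
  `synthetic_viable` fixture is the workhorse for simulation because it is
  viable across 15–35 °C by construction.
- Development-rate parameters for the two species were never published;
  fixture values are synthetic, chosen to reproduce the reported stage
  durations (~2.3 / ~9 / ~12 days for egg / larva / pupa near 25 °C), and
  are flagged as synthetic in the fixture files.
- Lethal temperatures (LT50/LT100) are the bracketed roots of
  M(T) = level on [−20, 60] °C (Brent's method, |M(root) − level| <
  10⁻⁶); a threshold is reported absent when the level is never crossed.
  For level = 1 the roots bound the clipped region where the raw
  exponential reaches 1.

## Fitting

Nonlinear least squares (`scipy.optimize.curve_fit`) with a deterministic
multi-start grid: log/logit-transformed linear fits seed the exponential
and logistic families; Brière thresholds are seeded just outside the
observed temperature range (these fits are sensitive to threshold starts).
Standard errors come from the information matrix when it is invertible;
fits that never converge are reported `converged=False`, never silently
returned.  Model comparison uses the Gaussian least-squares AIC,
`n·ln(RSS/n) + 2k` (a perfect fit maps to −∞ so it always wins), with ties
broken by higher R² and then fewer parameters.

The development-time distribution is fitted as one pooled binomial GLM
(statsmodels) of the empirical cumulative completion fraction on ln(time),
temperature-indexed intercepts plus a single shared slope — not as
per-temperature fits averaged — reflecting the same-shape assumption.

The five-parameter Stinner senescence curve is fit-capable but its
parameters are strongly collinear when only seven design temperatures are
available, so the package's recovery guarantee for it is stated on the
fitted curve (RMSE over the design range), not parameter-wise; the
well-identified forms carry the parameter-wise 3-SE guarantee.
Mortality fits are unweighted by default (replicate weights can be passed
explicitly).

## Cohort simulation

`simulate_cohort` advances one same-aged cohort (default 100 eggs, 50
repetitions at the estimation level) day by day:

- **Within-day cycle**: daily tmin/tmax are expanded to 24 steps by cosine
  interpolation (minimum at midnight, mean = (tmin+tmax)/2), the standard
  degree-day construction; development and senescence rates are averaged
  over these steps (rate summation).
- **Stage durations**: at stage entry each individual draws
  q = exp(logit(u)/b), the median-1 log-logistic quantile implied by the
  common slope b; the stage completes when accumulated physiological age
  reaches q.  b = ∞ gives deterministic durations.
- **Mortality allocation**: the daily death probability is
  1 − (1−M(T̄))^Δdev with Δdev the fraction of the stage completed that
  day (capped at completion), the only allocation for which whole-stage
  survival at constant temperature equals exactly 1−M(T) — the scale on
  which whole-stage mortality is measured.
- **Sex and adults**: sex is latent at the egg stage with P(female) = 0.5
  (the assigned female ratio), which is distributionally identical to
  assignment at emergence but keeps l_x monotone within a realization.
  Adult age is the normalized physiological age x = Σ S(T)·Δt; a female
  lays f(T̄)·[O(x_end)−O(x_start)] eggs per day and dies at her senescence
  threshold (deterministic x = 1 by default; a finite `adult_slope` makes
  it a log-logistic quantile).  Males are simulated identically without
  reproduction and are excluded from l_x·m_x.
- **Life table**: l_x is the surviving fraction of (latent) females;
  m_x is female eggs per living female per day, so R₀ = Σ l_x·m_x equals
  total female eggs / initial females exactly.  GRR is estimated as the
  mean realized lifetime female fecundity per adult female ("reproduction
  ignoring immature mortality"); the population-curve sum Σ m_x is
  identical in a synchronized cohort but carries an O(1/n) ratio bias
  (~1% at n = 100) when development is staggered, which would swamp the
  Monte-Carlo error of 50 repetitions.
- **Degenerate inputs**: a temperature series on which any stage's
  development rate is zero everywhere short-circuits to an explicit
  non-viable life table; cohort lifetime is capped at 5 years.

Reproducibility: all randomness flows through one `numpy` Generator; a
fixed seed reproduces the output bit for bit, and the pre-drawn
per-individual thresholds couple runs under parameter perturbations (so,
e.g., raising mortality pointwise can only remove individuals — the basis
of the monotone-harm test).

## Life-table parameters

Per repetition: R₀ = Σ l_x·m_x, r_m solves Σ e^(−r_m(x+0.5))·l_x·m_x = 1
by bisection on r_m ∈ [−1, 2] per day (tolerance 10⁻¹⁰, midpoint ages
x+0.5), λ = e^(r_m), T = ln R₀/r_m, D_t = ln 2/r_m.  These identities hold
exactly for the package's estimates by construction.  R₀ = 1 yields
r_m = 0 and an infinite doubling time; repetitions with no reproduction
are excluded, and if none reproduce the result is flagged non-viable
rather than NaN-propagated.  Means ± standard errors are taken across
repetitions.

Validation against observed data reports the Euclidean distance
√Σ(obs−sim)² per stage/variable; 0 is perfect agreement.

## Risk indices

- **ERI** counts the days (of exactly 365) on which M(T̄) < 1 for every
  immature stage.  The published index formula carries an ambiguous
  "net-reproduction" superscript; the base definition here is the
  immature-survival day fraction (matching the stated "index is 1 when all
  immature stages survive throughout the year" condition), with
  `require_reproduction=True` additionally demanding f(T̄) > 0.
- **T_x / GI**: the generation length from Julian day x is a deterministic
  median-individual forward pass (thresholds = 1): rate summation through
  egg → larva → pupa, then senescence-rate summation of the adult female
  to the age of 50% cumulative oviposition.  Whether the reference tool
  includes exactly this adult component is not documented anywhere we
  could verify; this definition is explicit and tested, not asserted to be
  the reference one.  Non-completion within 5 years yields an infinite
  T_x, which contributes 0 generations.  GI = mean over the 365 start days
  of 365/T_x; at constant temperature GI = 365/T_gen exactly.
- **AI** = Σ log₁₀ λ(T̄_x), with λ from the quadratic fitted to the
  simulated life-table λ values rather than a per-day re-simulation, and
  floored at 0.5/day (configurable) so that days outside the viable range
  bound AI below without −∞.  One AI unit is exactly a 10-fold annual
  multiplication.
- **Grids**: 12 monthly tmin/tmax values per cell are interpolated
  linearly between month midpoints (wrapped across New Year) to 365 daily
  values; a nodata cell in any input is nodata in every output.  ERI > 0.6
  (configurable) is exported as a binary establishment layer.

## Synthetic data generator

The generator emulates the constant-temperature design — 7 temperatures
(10, 15, 20, 25, 30, 33, 35 °C), 100 individuals × 5 replicates per
immature stage, 15 adult pairs per temperature — and the outdoor
validation year (daily minima within 9.14–16.68 °C, maxima within
18.84–37.66 °C, seasonal sinusoid plus clipped Gaussian noise).  Survival
is Binomial(n, 1−M(T)); durations are log-logistic with median 1/r(T)
(matching the logit-on-ln-time distribution the fitter assumes); daily egg
counts are Poisson with mean f(T)·ΔO(x) — the minimal noise model, with no
overdispersion.  What passing tests show is therefore internal
consistency: data generated under the model's own assumptions are
recovered by the fitting and simulation machinery.  Real rearing data
have features the generator deliberately omits — between-replicate
heterogeneity, overdispersed egg counts, measurement rounding coarser
than 0.1 day, non-log-logistic duration tails — so recovery rates here
are an upper bound on what field data would give.

Problem sizes used throughout the examples and checks (100 individuals,
50 repetitions, 200 refit runs per form, 20×20 rasters) are the package's
defaults for a desk-scale analysis; all scale linearly if increased.

## Known limitations

- No density dependence, host-plant effects, dispersal or interspecific
  competition; temperature is the only driver (no humidity/photoperiod).
- Constant-temperature fits are extrapolated to fluctuating regimes by
  rate summation; fluctuating-temperature data are used for validation
  only, never for fitting.
- The published life-table tables for the motivating species violate the
  standard identities (λ ≠ e^(r_m) as printed) and their mortality tables
  are partly garbled, so no numerical agreement with those tables is
  claimed; the package's estimates enforce the identities instead.
- Raster I/O is limited to the ESRI ASCII dialect (plain text); no
  GeoTIFF, projections, or DEM adjustment.
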