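# Methods

## Scope and model

The package projects national food demand — daily per-capita calorie
availability at household level, i.e. intake plus household waste — from
two exogenous drivers: per-capita income (US$2005 capita⁻¹ a⁻¹, market
exchange rates) and population. Food demand is split into vegetal and
animal-based calories via the animal share `C_LS = C_L / C_T`.

Two functional families are fitted for each of the two response
variables, reflecting genuinely different readings of the same history:

* Total demand `C_T = α(t) · I^β(t)` with either linearly drifting
  coefficients (`g_A`) or coefficients following a saturating
  Michaelis-Menten-type trajectory in time (`g_B`). In `g_B` the time
  trajectory `m(t) = ω₁ + ω₂(t−t₁)/(t−t₁+ω₃)` uses base year `t₁ = 1960`;
  everywhere else `t` is the plain calendar year. The `g_A`/`g_B`
  distinction matters mainly beyond the fitted range: `g_A` keeps
  drifting, `g_B`'s drift dies out.
* Animal share: `h_A` is log-linear in `ln I`, `t` and their interaction
  (animal calories remain a normal good; the negative interaction erodes
  the income effect over time); `h_B 
  = ρ(t)·√I·e^{−λ(t)I}` is a peaked
  curve under which animal calories become inferior at high incomes while
  the share stays non-negative. `h_B`'s interior maximum sits at
  `I* = 1/(2λ(t))`.

Storylines bind model pairs: materialistic worlds (A1, A2) take
`(g_A, h_A)`, sustainability-oriented worlds (B1, B2) take `(g_B, h_B)`;
custom pairs are allowed. Projection computes vegetal and animal demand
as `g·(1−h)` and `g·h`, so their sum equals the total by construction at
every stage.

## Estimation

* `g_A`: stage 1 regresses `ln C_T` on `ln I` per year (OLS); stage 2
  fits straight lines to the yearly `α* = ln α` and `β` series against
  calendar year. An alternative single-pass mixed model (statsmodels
  MixedLM, year-level random intercept and ln-income slope; yearly
  coefficients = fixed effects + BLUPs) is selectable; on low-noise data
  it agrees with the two-stage lines to within a few percent. The
  two-stage path is the default because it is transparent and because the
  stage-2 lines are themselves the reported quantities. MixedLM's default
  optimizer is unreliable for this variance structure; Powell is used
  with a fallback.
* `g_B`: per-year nonlinear least squares of `C_T = α·I^β` on the
  untransformed kcal scale (initial values: geometric mean of `C_T` for
  `α`, 0.1 for `β`), then nonlinear fits of the saturating trajectory to
  the yearly `α` and `β` series. The half-saturation constant `ω₃` is
  poorly conditioned — the reference `β` trajectory has `ω₃ ≈ −0.76`,
  a near-pole just before the first observation — so the trajectory
  fitter multi-starts from a deterministic `ω₃` grid (including values
  just right of the feasibility bound `ω₃ > t₁ − t_min`) and keeps the
  best converged solution. Near-constant series short-circuit to
  `ω₂ = 0` with a warning.
* `h_A`: OLS of `ln C_LS` on `{ln I, t, t·ln I}`; zero shares are dropped
  (log undefined) and counted. A single-year design is rejected as
  collinear.
* `h_B`: nonlinear least squares on the untransformed share. The start
  point comes from a coarse geometric grid over the decay rate `λ` with
  the level `ρ` solved in closed form at each grid point (both
  time-constant), followed by joint refinement of all four coefficients.
  Zero shares are retained.

All nonlinear fits use a sum-of-squares tolerance of 1e-10 and at most
10,000 function evaluations; observations are unweighted (one
country-year = one observation). Income must be strictly positive; share
evaluations outside [0, 1] are clipped with a warning in library use, but
the scenario engine treats any clipping as an error and aborts, because a
share above 1 would make vegetal demand negative.

## Calibration and aggregation

Projections are anchored to observed base-year (default 1990) values per
country, separately for vegetal and animal series so the additive
identity survives. Two modes:

* `converge`: linear blend `conv(X_t, C₀, y_s, y_e)` from the observation
  to the regression value by the convergence year (default 2100) —
  national peculiarities vanish, consistent with observed convergence of
  diets under globalization;
* `preserve`: each country keeps its base-year percentage deviation from
  the regression for all time.

On worlds where countries deviate ±20% in the base year, `preserve`
yields a larger cross-country dispersion of per-capita demand at 2100
than `converge`; the tests assert this ordering rather than any absolute
dispersion.

Energy totals use `E = C · P · k · d`, with `k = 4184 J/kcal`
(thermochemical calorie) and `d = 365 d/a` by default, reported in
10¹⁸ J a⁻¹. Both constants are explicit arguments because the reported
unit alone does not determine them. Regional aggregation uses
population-weighted means for per-capita variables and sums for energy
totals; world totals are invariant to the regional partition. Regional
gap-filling of missing historical cells uses the population-weighted
same-region same-year mean of reporting countries (unweighted available,
since the sources do not document the weighting), never altering observed
cells.

## Validation battery

* Goodness of fit: OLS of observed on modelled values (intercept, slope,
  r², F, p).
* Mann-Kendall trend test: tie-corrected variance, continuity-corrected
  normal approximation; trend slope defaults to the median of consecutive
  differences per year (the literal "differences between the values and
  their successors"), with the all-pairs Sen slope as an option. The
  partial variant conditions on a user-supplied covariate series through
  the rank-based covariance of the two MK scores (Libiseller-Grimvall);
  the conditioning covariate is deliberately not fixed by the package.
  The implementation is verified against a brute-force enumeration oracle
  over every short series with ties.
* Subsample bootstrap: default 1000 replicates, each refitting on a
  random 67% of complete data pairs drawn without replacement (replicate
  seeds derived from a single seed by counter, bit-reproducible),
  reporting coefficient ratios to the full-data fit and the held-out
  third's observed-vs-modelled r².

## Synthetic data

The generator's defaults emulate the historical panel's dimensions:
162 countries × 47 years (1961-2007), initial log income
~ N(ln 2000, 1.3), per-country geometric growth rates ~ N(0.02, 0.015)
drawn once per country so the cross-country income ordering persists,
log-normal populations with analogous persistent growth. Calorie
variables sit on a chosen generating surface (any of the four models,
reference coefficients shipped) times multiplicative log-normal noise
with σ = 0.1.

The noise is **country-persistent** by default: one log-normal factor per
country, constant over the years, representing persistent national
dietary peculiarities — the very deviations the convergence calibration
is built to absorb. This choice is not cosmetic: with independent
per-cell noise the yearly coefficient series of the two-stage fits jitter
so much that the stage-2 time-trend lines have r² near zero, whereas the
historical data show r² ≈ 0.96; persistent country noise reproduces that
smoothness. Independent noise remains available
(`noise_structure="iid"`).

What passing tests do and do not show: noiseless panels confirm that
every fitting pipeline recovers its generating coefficients essentially
exactly (self-consistency), and noisy panels probe identifiability under
realistic scatter. They do not validate the functional forms against real
diets, and several coefficients are intrinsically weakly identified at
this noise level: time-trend slopes of order 1e-5 per year (e.g. the
elasticity drift β₂) have information-limited standard errors of the same
order or larger regardless of estimator, and intercepts expressed at
calendar year zero inherit that uncertainty amplified by ~2000 years of
extrapolation. The share model `h_A`, whose coefficients are large, is
recovered to a few percent under the same noise; recovery failures for
the small trend coefficients are a property of the estimation problem,
not of the optimizer. The same weak identification shows up in the
bootstrap as wide ratio distributions (sd up to ~0.6) for the
extrapolated intercepts, so 100-replicate ratio medians carry Monte-Carlo
error of roughly two percent.

Scenario inputs are generated on the 1990-2100 grid in 5-year steps:
incomes continue each country's historical growth scaled per storyline
(A1 1.4×, B1 1.2×, B2 0.9×, A2 0.7×); population growth declines
linearly to zero at a storyline-specific peak year (A1 2045, B1 2050,
B2 2125, A2 2200) and turns negative afterwards, so globalized-world
population peaks inside the century. Missingness injection blanks cells
independently at a given rate for exercising the gap-filling step.

## Numerical and interface choices

* Missing data are NaN (empty cell or NA literal); zero is a valid-looking
  but invalid calorie value and is never used as a missing marker.
* Canonical file dialect: UTF-8 CSV, header row, long format, floats at
  12 significant digits; a write/read cycle is stable byte-for-byte from
  the second cycle on.
* Fitted parameters serialize to flat `model<TAB>name<TAB>value` lines.
* CLI stages (`simulate`, `harmonize`, `fit`, `project`, `validate`)
  compose through files; `project` writes a run manifest (config hash,
  constants, versions). Exit codes: 0 ok, 2 config, 3 data validation,
  4 numerical.
* Test problem sizes are deliberately modest (mostly 12-40 countries,
  shortened year ranges) with full 162×47 panels reserved for the
  recovery and bootstrap checks; fitting at full size takes on the order
  of a second per model.

## Known limitations

* No prices, trade, supply-side constraints or intake/waste split; income
  and time are the only drivers beyond population.
* Stepwise predictor selection (ANOVA/AIC) used upstream to choose the
  published functional forms is out of scope; the forms are taken as
  given.
* The partial Mann-Kendall covariate and the exact mixed-model structure
  behind the published fits are under-specified upstream; both are
  exposed as options without claiming either is canonical.
* Real FAOSTAT/WDI/CIESIN data access is out of scope; reproduction of
  published regional trend tables and scenario magnitudes requires those
  data and is replaced here by property-based and structural checks.
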