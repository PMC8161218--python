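# Methods

## The index

ETIS scores the thermal load on a sow as dry-bulb air temperature plus four
*equivalent temperatures* — increments of air temperature that would have the
same effect on the animal's heat balance as humidity, air movement, floor
conduction, and long-wave radiation:

```
ETIS = T + a·(RH−50)·T + e·u^c·(Ts−T) + D·(Ts−T)
         + R_rad·((Ts+273.15)⁴ − (T+273.15)⁴)
```

Assumptions baked into the structure:

- **Reference skin temperature.** `Ts` is fixed at 38 °C rather than taken
  from the animal, so the index is a pure function of the environment.
- **Humidity pivot at 50 %.** The humidity term vanishes at RH = 50 and
  scales with `T`, reflecting the growing weight of evaporative load at
  higher temperature.
- **Convection power law.** Convective exchange scales as `u^c` with
  `c = 0.6827`, a value specific to a *recumbent* sow (a standing pig is
  closer to 0.66). `u = 0` zeroes the term; so does `T = Ts`.
- **Floor and enclosure at air temperature.** Indoors, floor surface and
  mean radiant temperature track the air, so both substitution forms default
  to `T`; explicit floor / mean-radiant temperatures may be supplied per
  observation and enter their terms in place of `T`.
- **Kelvin only inside radiation.** All quantities are °C; the +273.15 shift
  appears only in the fourth-power radiation term.

The calibrated coefficient set (`ETISParameters()` defaults) is stored
verbatim: `a = 0.0006`, `e = −0.3132`, `D = −4.79` with a conduction
reference factor 1.0086 (the fitted conduction term is
`−4.79·(1.0086·38 − T)`, not zero at `T = Ts`), and `R_rad = 4.8957×10⁻⁸`.
These constants are not re-derivable from the regression coefficient ratios
by any stated rule, so they are canonical data, not computed values. An
optional two-coefficient radiation mode (`radiation_coef_skin`) allows
distinct skin-side and air-side coefficients, mirroring the raw regression.

On the calibration domain (T ∈ [21.9, 34.0] °C, RH ∈ [40, 90] %,
u ∈ [0, 0.29] m·s⁻¹) the fitted index is strictly increasing in `T` and
non-increasing in `u` whenever `T < 38 °C` — faster air cools a sow that is
warmer than her surroundings. Outside that domain the index extrapolates
smoothly but was not calibrated.

## Psychrometrics

Saturation vapor pressure uses the Magnus–Tetens form
`e_s = 6.1078·10^(7.5T/(237.3+T))` hPa — the same constants that appear in
the enthalpy benchmark, keeping the two consistent. Dew point is the
analytic inversion of that curve at the actual vapor pressure. Wet bulb
solves the psychrometer equation `e_s(Tw) − γP(T − Tw) = e`
(γ = 6.62×10⁻⁴ °C⁻¹, screen thermometer) by vectorized Newton iteration;
the Stull (2011) closed form is available as a fast path
(`method="stull"`) but deviates from the psychrometer solution by up to
~0.7 °C at hot, dry states, which is why the iterative solve is the
default. Dry-bulb inputs are validated on [−20, 60] °C; the saturation
curve itself accepts down to −100 °C so the dew points of valid very-dry
states remain evaluable. Both outputs respect `T_dp ≤ T_wb ≤ T` with
equality at saturation.

The instrument-to-wet-bulb conversion used for the original benchmark table
is unknown; any defensible approximation shifts wet-bulb-based comparison
indices in the second decimal. This is a genuine source of irreducible
disagreement when comparing against published correlation tables.

## Comparison indices

Twelve registry entries: eight THI variants (`thi_a` … `thi_h`, in the
conventional comparison-table order), BGHI, effective temperature (ET),
moist-air enthalpy (H), and ETIS itself. Each entry declares its required
inputs and native scale; Fahrenheit-based variants (`thi_d`, `thi_f`)
compute and report in °F because their published thresholds are
scale-specific. BGHI substitutes the dry bulb for a missing black-globe
temperature (indoor mean-radiant assumption). Two formulas circulate in
typographically corrupted form; the package evaluates reconstructed
versions by default — ET groups its wind correction as
`−(42 − T)·(u^0.66 − 0.2^0.66)`, zero at the 0.2 m·s⁻¹ reference speed, and
H uses the Magnus denominator 237.3 — while `strict_paper=True` evaluates
the printed text verbatim for fidelity checks.

## Calibration

The regression design follows the index structure with `Ts` already fixed:

```
y = b₀ + b₁T + b₂(50T) + b₃(RH·T) + b₄u^0.6827(38−T) + b₅·38 + b₆T
      + b₇(38+273.15)⁴ + b₈(T+273.15)⁴
```

This matrix is rank-deficient *by construction*: columns 2 and 7 are
identical, column 3 is proportional to them, and columns 6 and 8 are
constants collinear with the intercept (numerical rank 5). The solver
scales each column to unit norm, takes the SVD minimum-norm least-squares
solution, maps coefficients back, and reports rank and a condition
indicator. Individual coefficients are therefore one representative of an
affine solution family; fitted values are unique, and only the identifiable
combinations are interpreted:

- `a = b₃`, `e = b₄`, `R_rad = −b₈`,
- pooled T-linear mass `b₁ + 50b₂ + b₆ = 1 − 50a − D` → `D`,
- pooled constant mass → the conduction reference factor.

`assemble_etis_from_fit` exposes two conventions: `"paper"` returns the
canonical published constant set; `"direct"` applies the mapping above and
documents it in metadata. On noiseless index-structured responses the
direct mapping recovers the generating parameters to ~1e-13 and always
reproduces the fit's predictions.

R² is defined as the squared Pearson correlation between observed and
predicted values on whichever subset is evaluated — the scatter-plot
convention — which coincides with the usual definition on training data but
not necessarily on test data. The train/test split is a seeded random
permutation with `round(n·fraction)` training rows (1029 → 720/309);
datasets under 10 records are refused.

## Thresholds

Heat-stress categories anchor to THI breakpoints 74/78/82 (from sow
pregnancy-rate studies) transferred to the ETIS scale through the fitted
line `ETIS = 0.3533·THI + 6.9249`, giving boundaries 33.1 / 34.5 / 35.9 °C
after rounding to one decimal. Design choices:

- The intercept sign is taken positive: only `+6.9249` reproduces the
  published boundary table (0.3533·74 + 6.9249 ≈ 33.07 → 33.1).
- Boundaries are rounded to one decimal *before* comparison, matching the
  published table's precision; classification intervals are
  lower-inclusive (`33.1 ≤ ETIS < 34.5` is mild), so a value exactly on a
  boundary falls in the hotter category.
- Breakpoints and the line are configuration, not constants — genotype and
  region shift them — and `fit_thi_etis_map` refits the line from any
  aligned (THI, ETIS) sample.

Classification through the map agrees with THI-side classification
everywhere except within half a rounding width of a boundary, which is the
unavoidable cost of publishing rounded boundaries.

## Synthetic data generator

The generator emulates a summer barn campaign of 1029 paired
environment/physiology readings (its default `n`):

- **Marginals.** T, RH, u are truncated normals on the observed ranges
  ([21.9, 34.0] °C, [40.4, 89.8] %, [0, 0.29] m·s⁻¹) whose *underlying*
  location/scale are solved numerically (scipy `truncnorm` +
  `least_squares`) so the truncated distribution reproduces the target
  mean/SD (28.7/2.6, 65.8/10.0) — naive clipping would bias both. The air
  velocity targets (mean = SD = 0.07) are infeasible for any truncated
  normal, since a bounded support forces coefficient of variation < 1; the
  closest family member is used (achieved mean ≈ 0.0734, SD ≈ 0.0641) and
  the achieved moments are recorded in provenance.
- **Dependence.** A Gaussian copula couples T and RH (default correlation
  −0.3: humid mornings, hot dry afternoons; configurable in (−1, 1));
  u is independent. Marginals pass through the copula by inverse-CDF
  transform, so moment matching is exact regardless of the dependence knob.
- **Physiology.** Skin temperature is linear in ETIS with slope 1.0041 (the
  training-set index/skin relation); the intercept is anchored at
  generation time so the mean skin signal hits the campaign mean 34.9 °C
  over the *synthetic* climate (a fixed published intercept embeds the real
  campaign's joint distribution, which the copula only approximates; an
  explicit intercept overrides the anchor). Respiration rate follows
  `2.2137·THI − 135.98`, floored at 12 breaths·min⁻¹; core temperature
  follows `0.0454·THI + 34.873`. Noise SDs default to *calibrated*: solved
  so each response's squared correlation with THI matches the published
  values (0.6165 skin, 0.1386 respiration, 0.0972 core) given the realized
  THI variance — `σ² = var(signal)·(ρ²/R²_target − 1)` with
  ρ = corr(signal, THI).
- **Determinism.** One integer seed drives everything
  (`numpy.random.default_rng`; the physiology stream derives from a seed
  sequence so environment and noise draws never alias).

What the generator does **not** emulate: diurnal and spatial
autocorrelation, sow-level repeated measures, measurement error in the
climate sensors, and any nonlinearity in the true physiological response.
Tests passing on this generator therefore demonstrate the *pipeline* —
moment-faithful inputs in, correct coefficients and categories out — not
field validity of the index, which requires real campaign data.

## Numerical choices

- Wet-bulb Newton iteration: tolerance 1e-10 °C, ≤ 60 iterations (typically
  ~6); the solved function is strictly increasing so the root is unique.
- Least squares: `numpy.linalg.lstsq` with `rcond = 1e-10` after column
  scaling; the exact-duplicate columns produce true zero singular values,
  and scaling keeps the fourth-power columns (≈10⁹) from distorting the
  cutoff.
- Moment matching: `least_squares` on (mean, SD) residuals with the scale
  parameterized on the log axis; a fit is labelled exact when the residual
  norm is below 1e-6. Targets whose mean lies outside the truncation bounds
  are rejected as configuration errors.
- CSV numerics are parsed with Python's correctly rounded `float()` so
  write → read round-trips are bit-identical at full precision.
- Acceptance-scale runs use n = 10⁵ synthetic records, which puts the
  standard error of the air-temperature mean at ~0.008 °C; the test suite
  uses n ≤ 2×10⁴ per case.

## Known limitations

- The conduction constants (−4.79, 1.0086) are stored data; nothing in the
  package can re-derive them from a fit, and the `"direct"` convention will
  generally disagree with them on real (noisy, non-index-structured) data.
- Comparison-index values that need wet bulb depend on the psychrometric
  approximation chosen (second-decimal effects).
- The classifier's boundary behavior inherits the published one-decimal
  rounding; readings within ±0.05 °C of a boundary are effectively
  unresolvable.
- The index is calibrated for enclosed, mechanically ventilated barns over
  the ranges above; nothing constrains extrapolation beyond warning-free
  arithmetic.
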