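# Methods

## Scope and data model

`etobench` evaluates monthly reference evapotranspiration (ET₀) models on
12-row tables of climate normals: per month, maximum/minimum temperature
(°C), rainfall (mm), maximum/minimum relative humidity (%), wind run
(km h⁻¹), bright-sunshine hours (h day⁻¹) and class-A pan evaporation
(mm day⁻¹). All ET₀ values are expressed in mm day⁻¹. A monthly value is
treated as a representative day: astronomical quantities are evaluated on
the 15th of the month (non-leap calendar), a convention that changes
mid-latitude extraterrestrial radiation by well under 1 % relative to a
true monthly mean.

## Meteorological machinery (met_core)

All intermediates follow FAO-56 forms, the de-facto standard wherever a
formulation is not dictated by the individual model:

- saturation vapour pressure (Tetens): e_s(T) = 0.6108·exp(17.27T/(T+237.3)) kPa,
  with Δ = 4098·e_s/(T+237.3)²;
- actual vapour pressure: dual-RH form
  e_a = [e_s(T_min)·RH_max + e_s(T_max)·RH_min]/200 by default, or
  RH_mean·e_s(T_mean)/100 via `Conventions(ea_mode="mean_rh")`;
- atmospheric pressure P(z) = 101.3·((293−0.0065z)/293)^5.26 and
  γ = 0.000665·P, i.e. γ ≈ 0.0517 kPa °C⁻¹ at the packaged station's
  2218 m. A fixed override (`gamma_override`, e.g. the near-sea-level
  0.0677) is supported because applied studies sometimes use a tabulated
  constant regardless of elevation; which convention a given study used is
  often undocumented, so both are first-class;
- extraterrestrial radiation R_a and day length N from solar declination
  and sunset hour angle, with the hour-angle argument clamped so polar
  night degrades to R_a = 0 rather than a domain error;
- solar radiation by Angström–Prescott, R_s = (a + b·n/N)·R_a with the
  FAO-56 defaults a = 0.25, b = 0.50 (no local calibration is available
  for the packaged station); n/N is clamped to [0, 1];
- net radiation R_n = (1−α)R_s − R_nl with α = 0.23 (grass) and the FAO-56
  longwave term using clear-sky R_so = (0.75 + 2·10⁻⁵z)·R_a; R_n is floored
  at 0;
- Doorenbos–Pruitt mean daily percentage of annual daytime hours p,
  embedded as the standard 0–60° × 12-month table, linearly interpolated in
  latitude; southern latitudes reuse the table with a six-month shift. The
  table is only defined to 60°, and inputs beyond that are rejected;
- wind converted from km h⁻¹ to m s⁻¹ and, when measured away from 2 m,
  reduced by the FAO-56 log profile 4.87/ln(67.8z − 5.42);
- soil heat flux G = 0 by default (configurable): for monthly normals of a
  low-seasonality tropical site the month-to-month storage term is small
  against R_n.

Turc and Makkink take R_s in the historical cal cm⁻² day⁻¹
(1 MJ m⁻² = 23.884 cal cm⁻²) and Caprio in kJ m⁻² day⁻¹; the registry
records each model's dialect and the conversion is centralised.

## Baselines (reference_eto)

Pan-derived ET₀ is K_pan·E_pan with the Allen–Pruitt regression
K_pan = 0.108 − 0.0286u₂ + 0.0422·ln F + 0.1434·ln RH − 0.000631(ln F)²·ln RH
(u₂ in m s⁻¹, fetch F in m, RH in %), clamped to [0.3, 1.1]. The default
fetch is 100 m, which puts K_pan in the 0.77–0.83 band implied by the
packaged station's published series. A literal transcription variant with a
3.31·10⁻⁴ wind coefficient and a (ln F)⁻⁴ cross term circulates in the
applied literature; it is dimensionally inconsistent with the published
Allen–Pruitt coefficients, so it is available behind
`Conventions(kpan_variant="printed")` for audit but is not the default.

FAO-56 Penman–Monteith is implemented in its canonical grouping
ET₀ = [0.408Δ(R_n−G) + γ·900/(T+273)·u₂(e_s−e_a)] / [Δ + γ(1+0.34u₂)],
floored at 0. On the packaged normals it reproduces the station's published
monthly FAO-PM values within ±0.3 mm day⁻¹ (typically ±0.15).

## Empirical models (empirical_eto)

Eighteen models sit behind a uniform registry keyed by `model_id`, each a
pure function of one month's record and derived meteorology. Notable
conventions, each configurable through `Conventions`:

- **Hargreaves–Samani** uses the classic 0.5 exponent on the diurnal range
  by default; the 0.517 recalibration circulating in the literature is one
  keyword away (`hargreaves_exponent`). The classic exponent reproduces the
  packaged station's published January value (3.2 mm day⁻¹).
- **Trajkovic** is implemented literally as 0.0023·R_a·TD^0.424·(T+17.8)
  with R_a in MJ and no division by latent heat: that literal reading
  reproduces the published 5.7–8.1 mm day⁻¹ range, whose overestimation is
  exactly the behaviour the benchmark is meant to expose.
- **Schendel** and **Ivanov** consume a single RH, mean(RH_max, RH_min) by
  default (`rh_single="min"` selects minimum RH); **Papadakis** uses
  2.5·(e_s(T_max) − e_a) with the dual-RH e_a by default
  (`papadakis_ea="tmin"` selects e_s(T_min) instead).
- Raw outputs may dip below zero at cold extremes (Irmak, Tabari, Makkink
  offsets); they are floored at 0 with a month-level logged warning.

The latent heat of vaporisation is fixed at λ = 2.45 MJ kg⁻¹ (FAO-56
convention) through `SiteMetadata.latent_heat`.

## Evaluation statistics (evalstats)

For modelled M_i vs observed O_i over n paired months: FAC2 (fraction with
0.5 ≤ M_i/O_i ≤ 2), MB, MGE, NMB = Σ(M−O)/ΣO, NMGE, RMSE, sample Pearson
r, and Willmott's refined IOA with scaling constant c = 2 (the standard
value): IOA = 1 − A/B for A ≤ B and B/A − 1 otherwise, where
A = Σ|M−O| and B = c·Σ|O−Ō|. Pairs with O_i = 0 count as outside factor
two (the ratio is undefined); a constant series makes r and IOA undefined
and raises rather than returning NaN. Taylor coordinates use population
standard deviations so the law-of-cosines identity
crmsd² = σ_o² + σ_m² − 2σ_oσ_m·r holds to machine precision.

Rankings default to IOA descending — the single key that reproduces both
published performance orderings for the packaged station — with ties broken
by RMSE ascending then model id, making the order total and deterministic.
Error-type keys (MB, NMB, …) rank by absolute value ascending.

## Synthetic climate generator (datasets)

`generate_monthly_climate` emulates the *structure* of a tropical highland
monsoon climate: sinusoidal T_max/T_min cycles (T_max peaking near April,
T_min a month later), a monsoon month-set (default June–September) that
lifts mean RH by ~13 points and wind by ~3 km h⁻¹, sunshine decreasing
linearly in RH, and a pan-evaporation proxy increasing in temperature and
sunshine and decreasing in humidity, all with seeded Gaussian noise and
clipping into the record's validity domain. Defaults mirror the packaged
station's magnitudes. It does **not** emulate interannual variability,
rainfall occurrence processes, or realistic cross-correlations beyond the
ones listed — so generator-based tests demonstrate structural correctness
(determinism, validity, qualitative monsoon response, parameter recovery),
not real-world skill of any model.

## Numerical and test-design choices

- The packaged published tables are shipped as CSV package data, byte-stable
  across calls, and double as ordinary CLI inputs.
- The statistics are cross-checked against independent naive-loop oracles
  on 1000 random series pairs at 1 × 10⁻⁹; the meteorological primitives
  against closed-form re-evaluations at the same tolerance.
- Parameter recovery: when synthetic observations are one model's series
  plus N(0, 0.05 mm day⁻¹) noise, that model ranks first under every
  ranking key.
- Monthly reproduction bands: published monthly cells are checked at
  ±0.15 mm day⁻¹ (one unit in the last printed digit plus propagation of
  the inputs' own rounding). Two documented exceptions: the published
  Blaney–Criddle November/December cells imply a daytime percentage
  (~0.275) inconsistent with the one implied by the published Kharrufa row
  for the same months (~0.26, which matches the Doorenbos–Pruitt table) —
  those two cells are checked at a wider band; and the pan-observed series
  is checked at ±0.2 mm day⁻¹ because the station's implied monthly pan
  coefficient deviates up to ~0.05 from the Allen–Pruitt regression.
- Several published monthly rows (Schendel, Ivanov, Papadakis, Makkink,
  Priestley–Taylor, Abtew, and some Hargreaves months) are not derivable
  from the published inputs under any standard unit/RH convention we
  tried — the station's exact radiation source and humidity granularity are
  not documented. Those rows are used as *fixture data* for the evaluation
  layer (where every statistic reproduces) and are not treated as
  model-correctness targets; the structural properties above stand in for
  them.
- Hemispheric symmetry of R_a holds only after normalising out the
  Sun–Earth distance factor (a seasonal asymmetry of up to ~3 %); the test
  asserts the normalised identity.
- All computations on a 12-month table complete in milliseconds; the whole
  benchmark is deterministic, with the synthetic generator the only seeded
  randomness.

## Known limitations

- Monthly time step only; no daily or sub-daily stepping, no leap years.
- No local recalibration of model coefficients (deliberately out of scope:
  the benchmark evaluates the models as published).
- Humidity from dew point is not supported (inputs carry RH extremes).
- The Doorenbos–Pruitt table bounds usable latitudes to ±60°.
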