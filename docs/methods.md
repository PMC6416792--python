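# Methods

This note documents the models, estimators and numerical choices behind
each stage of the pipeline, what the synthetic generators do and do not
emulate, and the known limitations.

## Vapor physics

Saturation vapour pressure uses the Magnus form
e_sat(t) = 610.94·exp(17.625·t/(243.04 + t)) Pa (Alduchov–Eskridge
coefficients), valid −10…100 °C and within 0.4 % of standard psychrometric
tables over 0–50 °C — below the spread between table editions, so absolute
driving forces computed here may differ from table-interpolated ones by up
to ~1 %. Concentrations follow from the ideal gas law with
R = 8.314 J mol⁻¹ K⁻¹ and M_w = 18.015 g mol⁻¹; temperatures are °C at
every interface and Kelvin (offset 273.15) internally. The driving force
D = α_apo·C_sat(T_leaf) − α_air·C_sat(T_air) defaults to α_apo = 1 (hydrated
apoplast) and α_air = 0 (air over silica gel); both are configurable, and a
negative D is rejected rather than returned.

## Drying curves and g_min

Fluxes are per-interval finite differences of fresh weight, normalised by
the **total** (two-sided) projected leaf area and reported at interval
midpoints; weight-gain intervals are flagged, not dropped. Leaf
temperature, logged intermittently by IR thermometry, is linearly
interpolated to interval midpoints; without any logging, air temperature
plus a configurable offset (default 0) is used. RWD values within 2 % of
the physical bounds are clipped with a warning (0.1 mg balance noise near
saturation); larger excursions are errors.

The conductance–RWD curve is fitted with a two-segment model: *g* linear
in RWD while stomata close, then constant. All splits of the ordered
points with ≥2 decline and ≥3 plateau points are enumerated and the
total-RSS minimiser chosen — an exact search, so noiseless piecewise
input is recovered to solver tolerance. g_min is the plateau mean; RWD_SC
the intersection abscissa of the two segments. Guards: a series whose
overall slope is not significantly negative is "plateau-only" (no decline
to intersect); a tail segment that still declines both significantly and
substantially (>20 % of its level across its RWD span) means desiccation
never reached the cuticle-only phase and is rejected rather than reported
as a plateau. An optional 3-point median filter on *g* (off by default)
is available for spiky balances.

Leaf mass per area divides dry weight by the **one-sided** area
(total/2); leaf water content is (saturated − dry)/saturated. Note that
recomputing such traits from published species means gives
ratio-of-means, which approximates the published mean-of-ratios only to a
few percent.

## Arrhenius analysis

Points are x = 1/(T_air + 273.15), y = ln g_min, by default on
per-temperature replicate means (replicate-level fitting is available;
the air-temperature axis is the default because the bundled reference
fits are only reproduced on it, leaf-temperature input being available
via the series entries). Segments are ordinary least squares with
two-sided slope t-tests; a 2-point segment interpolates exactly (r² = 1,
no p-value).

Biphasic selection enumerates all contiguous splits with ≥2 points per
side, takes the total-RSS minimiser, and adopts it over the single line
when the F-test on the RSS reduction (2 extra parameters, df = n − 4) is
significant at α/n_splits. The Bonferroni factor compensates the
selection of the best split: with a plain α threshold the empirical
false-positive rate on flat-law synthetic studies (6 temperatures, means
of n = 8, CV 25 %) is ~13 %, clearly above the nominal 5 %; with the
correction it sits at ~5–7 %. The transition temperature is the
intersection of the two fitted lines converted to °C, and
E_p = −slope·R (kJ mol⁻¹) from the high-temperature segment.
`force_split=True` returns the best two-segment candidate regardless of
the test — the mode used in parameter-recovery experiments where the
truth is known to be biphasic (the F-test at n = 6 with df₂ = 2 has
limited power, ~30 % under the reference design, so conditioning recovery
on selection would bias it).

On the bundled reference means the two-segment intersection for the
water-spender falls at 39.5 °C. The original report of these data quotes
37.7 °C; no simple intersection convention on the published
per-temperature means reproduces that value (replicate-level or
leaf-temperature fits, which were not published, likely would). The
package reports the computed intersection and makes no attempt to match
the quoted figure.

Group comparisons follow the field's convention: Shapiro–Wilk on each
group, Welch's t when both pass (α = 0.05), Mann–Whitney U otherwise.
Identical samples short-circuit to t = 0, p = 1 (Shapiro is undefined on
constant data). Temperature trends use Spearman rank correlation on
replicate-level pairs.

## Wax and cutin statistics

Molar masses are resolved from homolog formulas per compound class
(CnH2n+2 alkanes … CnH2nO2 acids and esters; exact atomic masses), keyed
by total carbon number — for alkyl esters the summed acid + alcohol
carbons, consistent with C48–C58 ester labels. Cyclic/other components
have no homolog series and require an explicit molar mass; they are
excluded from the VLC chain-length distribution by default.

The MCL is reported in two conventions, always both: (i) the discrete
weighted median — the smallest chain length with at most half the weight
strictly below and at most half strictly above, with a tie flag at
exact-half splits (the inequalities admit multiple solutions and no
tie-break rule is standard); and (ii) an interpolated 50 % percentile —
cumulative weight assigned at each chain length, linear between
consecutive lengths — which produces the fractional MCL values
customarily quoted (e.g. 31.5 rather than 32). The exact interpolation
convention behind published fractional MCLs is not standardised;
reproducing specific published values would additionally require the
underlying full composition tables, so it is not asserted anywhere.

## FTIR melting analysis

The band maximum per frame is the grid argmax within the search window
refined by a parabola in **log**-absorbance over the upper half of the
band (exact for a Gaussian profile; falls back to the minimal 3-point
parabola, or the raw argmax when neighbours are non-positive). The
default window is 2910–2930 cm⁻¹, bracketing the CH₂ asymmetric stretch
(~2916–2924 cm⁻¹ in alkyl crystals). A flat window has no unique maximum
and raises.

The melting curve normalises the band shift between plateau estimates
(means of the first/last 3 frames) and reads onset/midpoint/completion at
the 0.05/0.5/0.95 crossings by linear interpolation, after denoising the
ν_max sequence with a 3-point median followed by a 3-point mean (identity
on monotone noise-free curves in effect: linear trends and, on a uniform
grid, sigmoid crossings are preserved). Plateau means taken on the tails
of an unsaturated sigmoid bias the midpoint by up to ~0.1 °C for a
transition ending near the top of the ladder; a four-parameter logistic
fit is always computed alongside as the alternative convention, and a
discrepancy flag is set when the two differ by >1 °C. A total shift below
1 cm⁻¹ (configurable) is reported as "no transition" rather than
analysed.

## Synthetic generators

All generators are pure functions of their config, seed included.

* **Drying**: conductance g(RWD) = g_min + g_s0·max(0, 1 − RWD/RWD_SC)^p
  (p = 1 by default, matching the fitter's piecewise-linear form; other
  exponents stress misspecification), integrated as dW/dt = −g·D·A by
  explicit Euler with 20 substeps per weighing (discretisation error
  ≪1 %). Defaults mirror a 25 °C run of a water-spender leaf
  (SW 0.82 g, DW 0.14 g, A 45 cm², g_min 6.9×10⁻⁵ m s⁻¹, g_s0 5×10⁻⁴,
  RWD_SC 0.14) weighed every 30 min for 12 h; Gaussian balance noise is
  added to observed weights (0.5 mg in the noisy experiments, five times
  the balance precision, to be conservative).
* **Temperature study**: 6 temperatures 25–50 °C, n = 8 replicates,
  lognormal mean-preserving noise with CV 25 % (the replicate scatter of
  gravimetric g_min assays); laws are single-line (E_p configurable, 0 =
  flat) or biphasic (flat-to-steep, continuous at the break; defaults
  E_p = 76 kJ mol⁻¹, break 38 °C).
* **FTIR**: one Gaussian band per frame (FWHM 12 cm⁻¹, 2 cm⁻¹ grid) whose
  centre runs 2918→2924 cm⁻¹ along a logistic (scale 3 °C, chosen so a
  melting range spans ~18–20 °C as observed for leaf waxes) over the
  reference ladder 24→48 °C by 4 °C then 48→94 °C by 1 °C; noise channels
  for absorbance and for band-position jitter.
* **Wax profiles**: two fixed species templates — alcohol-dominated
  unimodal (~4 µg cm⁻², <2 mol % ≥C40) and ester-rich bimodal
  (~29 µg cm⁻², ~30 mol % ≥C40) — with lognormal coverage scatter
  (CV 10 %).

What the generators do **not** emulate: wound-sealing and early-phase
stomatal dynamics beyond the closure power law, energy-balance leaf
temperatures (the leaf–air offset is a fixed schedule), GC co-elution and
baseline artefacts, multi-band IR spectra, or drift/autocorrelation in
balance noise. Closed-loop recoveries therefore demonstrate estimator
correctness under the assumed noise structure, not robustness to every
artefact of real instruments.

## Problem sizes and determinism

The validation experiments use 20 leaves for noisy g_min recovery, 200
seeded studies for the false-positive calibration, 100 for biphasic
parameter recovery and 100 for FTIR midpoint recovery — sizes at which
the binomial/median uncertainties are small relative to the documented
tolerances while the whole suite runs in seconds. JSON reports are
written with sorted keys and full-precision floats, so identical inputs
give byte-identical outputs.

## Limitations

* The breakpoint fitters assume exactly one transition; multi-phase
  drying curves or Arrhenius plots with two breaks are out of scope.
* The Arrhenius F-test at the reference design (6 temperature means) has
  low power; non-selection of a biphasic model is weak evidence of
  linearity.
* Mole-fraction statistics depend on correct compound-class assignment;
  unknown classes must carry explicit molar masses.
* The FTIR stage analyses a single band; strongly overlapping bands
  (e.g. CH₃ asymmetric stretch shoulders) would need deconvolution, which
  is deliberately not provided.
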