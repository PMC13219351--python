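# Methods

## Scope and data model

The package operates on plot-scale experiments: a field of rectangular plots
under known irrigation treatments, observed at a handful of growth stages
(jointing, heading, grain filling for winter wheat). Everything is reduced to
one row per plot × stage: band-mean reflectance, canopy-temperature pixel
statistics, AIH crop height, inverted LAI, ET components and plant moisture
content. All grids use a half-open pixel model with the origin at the
upper-left corner and a `(x_left, y_top, resolution)` transform; pixels join
plots by the center-in-polygon rule (area weighting is deliberately out of
scope). Temperatures are °C throughout; Kelvin appears nowhere.

## Evapotranspiration model

Daily crop ET follows the dual-crop-coefficient decomposition
ET_c = (K_s·K_cb + K_e)·ET₀ with ET₀ from the daily Penman–Monteith form.
Dynamic behaviour enters through three substitutions:

* the tabulated basal coefficient (default mid-season K_cb,tab = 1.15 for
  wheat; static comparison values 0.25 / 1.15 / 0.30 for initial / mid /
  late) is climate-adjusted by
  (h/3)^0.3·[0.04(u₂−2) − 0.004(RH_min−45)] — skipped below 0.45 where
  sparse canopies make the correction meaningless;
* canopy density scales it as
  K_cb,a = K_c,min + (K_cb,adj − K_c,min)(1 − e^(−k·LAI)) with attenuation
  k = 0.7 and bare-soil minimum K_c,min = 0.15 (documented range 0.15–0.20);
* water stress enters as K_s = 1 − CWSI from the thermal index.

**One deliberate disambiguation:** writing the stressed basal coefficient
K_cb = K_s·K_cb,a *and* multiplying by K_s again in ET_c would square the
stress response. K_s is applied exactly once; the stressed value is what
feeds K_c,max, f_c and K_e, so soil evaporation sees the same canopy the
transpiration term does.

Soil evaporation uses the standard two-stage reduction: K_r = 1 while
cumulative depletion D_e ≤ REW, then (TEW − D_e)/(TEW − REW), with
sandy-loam defaults REW = 8 mm, TEW = 22 mm (both configurable). The wetted
fraction f_w defaults to 1.0 (traveling sprinklers wet the whole surface);
D_e resets to zero on configured wetting events and advances by each day's
K_e·ET₀. Depletion is tracked per plot. Δ, γ, e_s, e_a are accepted directly
from the weather table; psychrometric helpers derive Δ and γ from
temperature and standard pressure when absent.

## Thermal indices

Wet/dry reference temperatures are linear-interpolation percentiles
(defaults 0.5% / 99.5%) of the raw in-plot pixel values — no histogram
binning, which makes the estimate bin-width free — computed per plot, not
per scene. CWSI = (T_c − T_wet)/(T_dry − T_wet) is clipped to [0, 1] with
clip counts logged; the air temperature for ΔT is the station daily mean of
the flight date (overpass-hour temperature is not modeled).

## Vegetation indices

Eighteen indices from four bands (G, R, RE, NIR). Three printed-formula
dialects are resolved explicitly and flagged in the code: RDVI defaults to
the canonical (NIR−R)/√(NIR+R) with an as-printed switch reproducing the
NDVI-duplicate variant; MRETVI uses the minimal balanced bracket reading
1.2·[1.2(NIR−G) − 2.5(RE−G)]; kNDVI is tanh(((NIR−R)/2σ)²) with
σ = 0.5(NIR+R). CI_G / CI_RE are exposed under both their short and long
aliases. Undefined values (zero denominators, missing canopy temperature
for VSWI) propagate as NaN and drop out of correlations pairwise, so
bare-soil plots do not abort a scene. Feature screening ranks indices by
|Pearson r| with PMC, optionally averaged within stages so a feature must
perform across the season; ties break alphabetically. A footnote constant
α = 0.12 attached to the index table is used by none of the listed
formulas and is left unimplemented.

## Canopy structure

Crop height: ground returns from the bare-soil survey fit a least-squares
plane; normalized heights z′ = z − ground(x, y) below −5 cm are dropped
(counts logged). The AIH estimate is the 95th percentile of z′ by default
(90/99 available). With normalization putting the terrain at z′ = 0, the
lower boundary defaults to the ground datum itself rather than the 0th
percentile of returns — a pure-canopy cloud still reads as its canopy
height; a nonzero lower percentile switches to the percentile difference.

LAI: a seeded random forest (500 trees, unlimited depth) on six
structure-sensitive indices (RDVI, OSAVI, VIopt, MNLI, SAVI, NDVI), with a
25% held-out split for the reported R²/RMSE/nRMSE and a refit on all data
for prediction; predictions are floored at zero. Recovery is evaluated with
the three stages pooled: within a single stage the generator's LAI spread
is envelope-constrained to a few tenths, so a within-stage R² mostly
measures measurement noise, not model skill.

## PMC regression

Five combos (VIs / ET / VIs+ET / VIs+TIs / VIs+TIs+ET) × four regressors.
The spectral block is the six moisture-sensitive indices (NGI, CI_G, VSWI,
NDWI, MRETVI, NLI); the ET feature is stage-cumulative ET_c by default.
Hyperparameters come from a seeded random search scored by inner 3-fold
pooled RMSE (PLSR components 1–9, BPNN one ReLU hidden layer of 4–128
units, RFR 100–800 trees and 1–all max features); SVR is deliberately not
searched — RBF kernel, C = 1.0, γ = 1/n_features. Features are standardized
inside each training fold for PLSR/BPNN/SVR and left raw for RFR. Accuracy
is reported on pooled out-of-fold predictions of a seeded 5-fold outer
split, since a single number per stage × algorithm × combo is wanted;
per-fold R² values are retained. The exact train/test protocol behind
published single-value accuracy tables is rarely fully specified; pooled
out-of-fold evaluation is this package's declared convention.

## WUE and irrigation thresholds

WUE in kg/m³ is biomass (g/m²) over cumulative transpiration (mm); the
units cancel to the ratio directly (1 mm = 1 L/m²). Cumulative
transpiration is the K_s·K_cb,a·ET₀ component summed from emergence, with a
config switch for total ET_c. Three functional forms are fitted per
treatment × stage; the power form a·x^b is initialized from the log–log
regression and refined by nonlinear least squares. Thresholds are the
concave-quadratic vertex −b/(2a) rounded to one decimal; a vertex outside
the observed PMC range clips to the nearest endpoint and convex fits report
the better endpoint, both flagged rather than presented as interior optima.
The prescription rule irrigates when predicted PMC < threshold − deadband
(deadband 0 by default; equality holds).

## Synthetic experiment

The generator encodes the causal chain the analysis assumes. Irrigation
depth (W1 282 mm … W6 0 mm, 30 plots each of 1.4 m × 4 m by default) sets a
latent water status s ∈ [0, 1] (depth normalized to the deepest treatment
plus Gaussian noise, σ = 0.03). From s:

* **PMC** = base + span·s per stage (0.70+0.20s, 0.62+0.22s, 0.48+0.24s),
  declining stage over stage and spanning roughly 48–90% — wide enough
  that regression skill is not noise-limited, and bracketing realistic
  stage means (~0.80/0.73/0.60);
* **LAI and height** are stage means shifted by s and clipped to the field
  envelopes (LAI 3.10–3.59 / 5.09–5.34 / 4.78–5.15; height 0.38–0.61 /
  0.63–0.91 / 0.62–0.96 m);
* **canopy temperature** T_c = T_a + 8(1 − s) − 2 °C: well-watered
  canopies sit ~2 °C below air, rain-fed up to ~6 °C above;
* **biomass** is exactly wue_true × cumulative transpiration
  (Σ K_s·K_cb,a·ET₀ over the generated weather), so the WUE inversion is an
  identity on noiseless draws — the package's strongest internal check.

Scenes: reflectance mixes a soil and a dense-canopy endmember linearly in
LAI/6 with per-pixel noise (σ = 0.01), guaranteeing the NDVI-family–LAI
correlation without radiative-transfer machinery (no PROSAIL); thermal
pixels are Gaussian about the plot canopy temperature (σ = 0.8 °C) on a
soil background 6 °C above air; canopy point heights are Beta(6, 2) draws
rescaled by that distribution's own 95th percentile so the AIH-95 estimate
is unbiased by construction (500 canopy + 100 ground points per plot, on a
gently tilted plane). Weather is a 90-day spring series (T ramping 9→22 °C,
Rn 9→14 MJ m⁻² d⁻¹) with vapor pressures derived from the implied daily
min/max temperatures so e_s ≥ e_a always holds. All draws flow from one
root seed through named substreams, so layouts, weather, truth and scenes
regenerate independently and byte-identically.

**What the generator does not emulate — and what passing tests therefore do
not show.** Within-plot thermal pixels are symmetric Gaussians, so per-plot
percentile bounds straddle the mean and CWSI hovers near 0.5 regardless of
stress; on synthetic scenes the stress signal reaches the regression
through ΔT and the reflectance, not CWSI, and the raster-derived CWSI
mostly exercises plumbing, not discrimination (real canopies have skewed
mixed-pixel distributions that do discriminate). Leaf-level geometry,
spectral saturation at high LAI, sensor view-angle effects and spatial
autocorrelation between neighboring plots are likewise absent. Synthetic
recovery results bound implementation correctness, not field accuracy.

## Numerical choices and degenerate inputs

Percentiles use linear interpolation everywhere. CWSI with coincident
bounds raises (or flags the plot degenerate in whole-scene runs). A
constant LAI target flags the model degenerate with NaN R². Zero-variance
feature columns score |r| = 0 with a warning. Quadratic/linear fits use
`numpy.polyfit`; the acceptance refit of printed-precision coefficients
recovers them to ~1e-11. ET₀ and ET_c are floored at zero; f_c is clipped
to [0, 0.99] so the exposed fraction never vanishes entirely.

## Problem sizes

The test suite and acceptance script run the full design — 180 plots,
three stages, 90 days — for the campaign-level checks, and 12–30-plot
configurations for end-to-end pipeline tests; these sizes give stable
cross-validated metrics (sampling error on R² well below the margins
asserted) while keeping runs compact. The pipeline's default PMC matrix
runs RFR only with no hyperparameter search; the full 4-algorithm × 5-combo
matrix with search is available through the configuration.

## Known limitations

LAS point clouds are not read (XYZ CSV only); no CRS handling beyond a
local planar frame; no orthomosaic stitching or radiometric calibration —
inputs are assumed preprocessed to reflectance/°C; the energy-balance
(theoretical) CWSI baseline and root-zone depletion K_s are out of scope
(the stress factor is CWSI-only); pan-coefficient ET₀ validation is not
implemented. Reported field-study accuracy tables are not reproducible
without the underlying field data; the synthetic recovery suite is the
declared substitute.
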