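# Methods

## The estimation problem

Ground-level NO₂ relevant to exposure assessment is inferred from satellite
tropospheric vertical column densities Ω [10¹⁵ molec cm⁻²] through a
chemical-transport-model scaling,

    S(x, t) = Ω(x, t) · R(x),    R = S_model / Ω_model  [ppb per 10¹⁵ molec cm⁻²],

followed by population weighting and trend estimation. The column record
spans three instruments with footprints of 3.2° × 0.4°, 0.6° × 0.3° and
0.8° × 0.4° (lon × lat; ~111 km per degree) and eras that overlap by one to
five years. The central methodological problems — and the package's subject —
are (a) making those records spatially and radiometrically consistent, and
(b) correcting annual means for the seasonally selective loss of cloudy and
snow-covered scenes.

## Synthetic world

Every external input is generated with known ground truth. The surface truth
factorises as

    truth(x, year, doy) = base(x) · (1 + g_r/100)^(year − y₀) · a_{r,year} · s(doy)

with `base` a background plus Gaussian urban hotspots, `g_r` the configured
regional trend in %/year (geometric), `a` a mean-one lognormal region-year
anomaly (sd 5%) emulating meteorologically driven interannual variability,
and `s` a cosine seasonal cycle (amplitude 0.35 of the annual mean, peak in
mid-January). Days are sampled every 5th day of the year (73 per year),
equally spaced so the seasonal cosine sums to exactly zero and annual truth
means obey the configured geometric trends exactly — this is what makes
closed-form oracle tests possible.

The surrogate CTM block-averages the truth to a 2.4° × 2.4° model grid (the
coarse-model scale of global chemistry simulations; chosen to divide the
default window exactly, and configurable), carries a fixed spatially varying
surface-to-column ratio (0.4 ppb per 10¹⁵, ±30% smooth pattern), and layer
partial-column profiles whose surface fraction is mildly enhanced where the
surface field is high. Retrievals are distorted by the sensor's averaging
kernel applied to the model profile, so the standard a-priori-replacement
correction — column × Σx / ΣAx — inverts the distortion exactly in the
noise-free limit.

Sensors observe one longitude band (extent/revisit) per day. Footprint
columns are area-weighted means of the true fine column over the rectangle,
times the kernel distortion, an inter-sensor calibration bias (default 1.10
for the late sensor, giving the cross-calibration something to remove), and
multiplicative Gaussian noise (sd 0.25–0.30, truncated at −90% so columns
stay positive). Cloud radiance fractions are Beta-distributed with a
seasonally varying mean (0.30 summer, 0.55 winter) so QC losses correlate
with season; snow covers cells poleward of a threshold latitude outside a
day-of-year window jittered ±10 days per year.

Population is generated on a 2× finer grid as log-normal urban peaks around
the hotspots plus a rural background with multiplicative texture, aggregated
by summation (totals conserved exactly) at 5-year snapshots with mild
regional growth. Stations sample the truth at their grid cell times a
lognormal local bias and a site-class factor (traffic sites biased highest —
they exist to be excluded).

### What the generator does not emulate

Real retrieval spectroscopy, stratosphere–troposphere separation, orbit
geometry, meteorology-driven day-to-day variability, within-cell population
heterogeneity, and spatially correlated retrieval errors. Passing tests
therefore demonstrate the correctness and internal consistency of the
analysis chain under controlled conditions, not the accuracy of any real
satellite product.

## Harmonization

The fine sensor is the reference and defines the record's effective
resolution. Its 2003–2005 mean provides the downscaling ratio
`fine_ref / smoothed_ref`; coarse-era annual means (through 2003) are
multiplied by it, transferring fine texture under the persistence assumption
that relative spatial gradients change slowly. Late-era annual means (2012)
are scaled by the per-cell long-term (2007–2011) reference/target ratio,
which removes any uniform inter-sensor bias exactly; the ratio is clipped to
[0.1, 10] against noisy low-signal cells. Whole years are assigned to single
sensors (coarse through 2003, reference 2004–2011, late sensor 2012).

**Smoothed reference.** The classic choice smooths the reference with a
footprint-sized boxcar (3.2° × 0.4°, rounded up to odd cell counts: 33 × 5).
This package's default instead applies the coarse sensor's own observation
operator to the reference field (`smoothing="sensor"`;
`observation_model.sensor_smooth` enumerates the sensor's deterministic
placement-offset cycle with equal weights). The reason is quantitative: an
oversampled long-term mean smears a field with the footprint *convolved with
the footprint-centre density*, which is wider than the footprint itself and
varies with position in the sensor's swath-band pattern. Using the plain
boxcar as the "reproduction" of the coarse sensor leaves a several-percent
population-weighted mismatch between downscaled coarse-era years and native
reference years — a step at the sensor boundary that aliases directly into
trend bias. The operator-consistent smoothing removes the mismatch by
construction; the boxcar remains available (`smoothing="boxcar"`) and is the
tested form of the `boxcar_smooth` primitive.

Continuity is diagnosed with per-pixel z-scores of consecutive-year
differences at the hotspot ("major city") pixels: z = (d_boundary − mean d) /
sd(d), sample sd, z ≡ 0 for constant-difference series; the reported score is
the fraction of cases within 1.5 sd.

## Sampling-bias correction

Annual means over retrieved days are biased where NO₂ covaries with cloud or
snow season. The correction multiplies each cell-year by

    f = mean over all days of model surface / mean over retrieval days,

computed from the surrogate's daily surface resampled to the analysis grid.
The generic primitive (`sampling_correction_factor`) takes a binary
retrieval-day mask, as in the classic formulation. The pipeline uses the
weighted generalisation (`sampling_correction_factor_weighted`): because
annual column means weight days by summed footprint overlap, a cloudy-season
day that lost half its footprints is *down-weighted*, not merely missing,
and the correction must compare the all-day model mean with the model mean
under the same weights. With binary weights the two coincide. The correction
is applied to the harmonized annual mean of each year using that year's
assigned sensor's weights; cells with fewer than `min_days = 5` valid days
(echoing the five-coincident-observations station rule) are masked.

## Metrics and trends

PWM uses linearly interpolated population between 5-year snapshots (clamped
outside the range); masked cells drop out of both sums (weight
renormalization). Weighted percentiles interpolate linearly between adjacent
cells in cumulative-population space; the CDF starts at fraction 0 at the
region minimum. Reported percent changes round half away from zero and
always carry the unrounded value alongside.

Trends are plain OLS on annual means with years centred for numerical
stability; CI = slope ± t(0.975, n−2)·SE; two-sided t-test p-value; relative
trend = 100·slope/mean with the same transform applied to the CI ends.
Degenerate contracts: a constant series has slope 0 and p = 1; an exact
nonconstant fit has SE 0 and p → 0. Sub-period trends divide by the
*full-record* mean. Significance is p ≤ α with α = 0.01 (the boundary value
counts). No autocorrelation correction is applied by default; a Newey–West
flag (statsmodels HAC) exists for sensitivity analyses. Station comparison
requires ≥ 5 satellite-coincident observations per year in ≥ 15 years,
excludes traffic sites, averages stations sharing a pixel, and compares
relative trends of normalized series, so multiplicative station bias cancels.

## Parameter recovery and the definition of "truth"

The recovery study re-runs the full pipeline on replicate worlds and asks
whether each region's estimated relative trend CI covers the truth. The
configured trends are geometric, but the estimator is linear: the OLS
relative trend of an exact geometric series differs from the geometric rate
by construction (≈ +7.5 vs +6.7 %/year over 17 years). The recovery target
is therefore the *same OLS estimator applied to the deterministic truth PWM
series* (no noise, no anomalies, same population weighting), so the study
measures pipeline-induced error rather than the linear-vs-geometric
convention gap.

## Numerical choices

- Overlap areas: planar rectangles × cos(latitude) of the cell row; per-axis
  overlaps below 1% of the cell extent are dropped (sliver control).
- Negative noise-driven columns are retained through regridding and
  averaging (clipping would bias low-signal means); only final annual
  surface means are floored at zero.
- Downscaling ratio floor: below 5% of the global-mean smoothed reference
  the ratio is 1 (no texture transferred where the reference is too weak).
- Snow window: each year contributes its longest snow-free run; the default
  intersects runs across years ("shortest snow-free season"), guaranteeing
  identical seasonal sampling across sensor eras; a per-year mode exists.
- Model-to-analysis-grid resampling is nearest-neighbour block assignment:
  fine spatial texture comes from the satellite, not the model.
- One master seed; all streams (anomalies, snow jitter, population texture,
  stations, per-sensor noise/cloud/offsets) derive from it through named
  `SeedSequence` children, so runs are bit-reproducible.

## Study conditions and problem sizes

The default window is 9.6° lon × 4.8° lat at 0.1° (96 × 48 cells) — the
smallest extent commensurate with all three footprint sizes — over 1996–2012
with 73 sampled days per year; four quadrant regions carry trends of +6.7,
−4.7, −2.5 and −2.1 %/year with two hotspots each, placed near region
centres so coarse footprints do not mix regions with different trends. The
recovery study uses 50 replicate seeds. These sizes are the package's
desk-scale study conditions; all thresholds (cloud 0.5, min-days 5,
reference periods 2003–2005 and 2007–2011, α = 0.01) keep their study
defaults throughout.

## Known limitations

- The truth's spatial pattern is static up to regional factors, which is the
  regime where ratio downscaling is exact in expectation; worlds with
  migrating sources would degrade coarse-era years in ways the continuity
  z-score only partially reveals.
- The surrogate CTM is derived from the truth, so the surface conversion and
  sampling correction carry no model error; in reality both are major error
  sources.
- With footprints aligned to grid cells and separable geometry, regridding
  is exact; real scan geometries introduce projection errors not modelled
  here.
- Station records are complete by construction; the coincidence rules are
  exercised through the satellite masks, not through station gaps.
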