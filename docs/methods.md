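# Methods

## Sensor model and conventions

The radiometric model maps raw 16-bit counts to absolute spectral radiance
(W/m²/sr/nm):

```
L = V(x, y) · (a1/g) · (DN_norm − DNBL_norm) / (te + a2·y − a3·te·y)
V(x, y) = 1 / (1 + k0·r + k1·r² + k2·r³ + k3·r⁴ + k4·r⁵ + k5·r⁶)
```

- DN and the black level are normalised by the fixed constant 65536.
- Coordinates are 0-based `(row, col)`; rectangles are half-open. The row
  index `y` in the exposure denominator is 0-based (the camera vendors do
  not document the base; the simulator uses the same convention, so the
  chain is self-consistent and the choice is visible here rather than
  buried).
- `r` is the Euclidean distance in pixels between pixel centres and the
  optical centre `(cx, cy)` carried in the tags. The vignette polynomial is
  evaluated in Horner form for numerical stability.
- Pixels whose DN falls below the black level (possible under read noise)
  would yield negative radiance; they are clamped to 0 and counted in the
  `RadianceImage.n_clamped` QA field rather than silently propagated —
  radiance is physically non-negative, and a large clamp count flags a
  corrupt dark level.
- A non-positive row denominator means the exposure tags are corrupt; the
  conversion refuses and names the first offending row.

Metadata travels in a versioned JSON sidecar validated by a pydantic
schema, one per capture, instead of proprietary EXIF/XMP dialects: sidecars
are diffable, bit-exact, and exercised directly by tests. Tags are stored
per band because the five imagers expose independently; the simulator
generates per-band exposure times to keep that path honest.

## Panel extraction

Panel radiance is the mean over the panel AOI after two guards:

- The user-supplied AOI is shrunk to its central 50 % area (each side
  scaled by √0.5). Real calibration boards are bordered by white paper and
  barcodes; a conservative central crop avoids mixed pixels without
  requiring automatic panel detection.
- Pixels at DN ≥ 65280 (99.6 % of full scale) are treated as saturated and
  excluded; a shot with more than half its AOI saturated is rejected
  outright. QA statistics (pixel count, standard deviation, saturated
  fraction, clamp count) accompany every extraction; a high AOI standard
  deviation is surfaced but not auto-rejected, since no principled
  threshold exists for panel non-uniformity.
- When a mission has several usable calibration shots (typically one
  before and one after the flight), the mission panel radiance is their
  unweighted mean — symmetric, and agnostic about whether pre- or
  post-flight conditions are more representative.

## Cross-sensor regression and correction factor

For a Lambertian panel of reflectance ρ, irradiance and radiance
interconvert by `E = π·L/ρ`; the DLS reading converts by `L = E/π`. Each
calibration shot therefore yields one `(Irr_DLS, Irr_CRP)` pair per band,
and the relationship `Irr_CRP = a·Irr_DLS + b` is fitted by plain ordinary
least squares — the packaged defaults are a single universal fit across
weather conditions, and OLS keeps them reproducible and interpretable. A
Theil–Sen option (`robust=True`) exists for outlier-heavy sample sets but
is off by default. Fits with fewer than two distinct DLS values are
refused.

The mission correction factor

```
Cor = a / (1 − b·ρ_CRP / (π·L_CRP))
```

is applied as a float64 scalar per band to float32 rasters (the factor's
precision dominates the raster's). Its algebra implies, and tests assert:
`Cor → a` as `L_CRP → ∞`; `Cor = a` exactly when `b = 0`; `Cor > 1`
whenever `a > 1` and `b > 0`; and a denominator ≤ 0 (intercept dominating
the panel radiance) marks an invalid calibration image and raises. With
the packaged coefficients the per-band factors order blue < red edge <
red < green < NIR everywhere on the plausible irradiance range, with the
grid minimum ≈ 1.014.

An optional pre-multiplier hook on the DLS irradiance is reserved for
sun-angle (Fresnel) compensation of first-generation DLS diffusers; no
published closed form exists, so the default is the identity and nothing
is guessed.

## Indices and composites

NDVI, ReNDVI and NDRE are normalised differences on strictly positive
band pairs, hence bounded in [−1, 1]. Pixels where both bands are zero get
NaN (nodata), not 0 — zero is a meaningful index value. The vegetation
mask defaults to ReNDVI ≥ 0.1, which separates water, soil and concrete
from vegetation in the simulator's spectra and is configurable.

Display composites use histogram normalisation: one (2.5 %, 97.5 %)
percentile pair computed from the *pooled* pixels of the three routed
bands (never per band, preserving white balance), followed by a linear
stretch to 8 bits with clipping. Percentiles interpolate linearly between
order statistics — the most common convention, stated here because the
choice moves the bounds by a fraction of a pixel value. A constant image
degenerates the stretch; it renders mid-gray with a warning. CIR routing
is (NIR, red, green), the standard false-colour infrared mapping.

## Forward simulator

The simulator emulates the conditions the correction model is built for:

- **Scenes** are class rasters (marsh, grass, forest, soil, water,
  concrete) with fixed 5-band spectra; vegetation spectra satisfy
  ρ_NIR > ρ_RedEdge > ρ_Green > ρ_Red. Surfaces are Lambertian
  (`L = E·ρ/π`) with no BRDF or adjacency scattering; an optional additive
  NIR radiance offset emulates path-scattering excess for robustness
  tests.
- **Scenarios** set the sky irradiance: the sunny preset holds near the
  1.8 W/m²/nm peak, the cloudy preset near 0.5 W/m²/nm — the span observed
  between overcast and clear field conditions — with a mild within-mission
  drift and a fixed decreasing spectral shape toward the NIR.
- **The cross-sensor offset is the ground truth of the experiment**: the
  DLS records the sky irradiance `E_sky` exactly, while the ground panel
  receives `a_true·E_sky + b_true` (path-scattered extra light). Defaults
  for `(a_true, b_true)` equal the packaged regression coefficients, so
  simulated missions exercise realistic correction magnitudes, panel-only
  reflectance is biased low by `E_sky/E_panel`, and the correction factor
  recovers truth exactly in the noise-free, stationary-illumination limit.
- **Counts** invert the sensor model, add optional Gaussian read noise
  (default σ = 20 DN, a typical CMOS read-noise scale at 16 bits), and are
  rounded/clipped to uint16. Quantisation bounds any radiance recovery at
  the half-count level (~10⁻³ relative for the darkest scene class with
  the default tags); the continuous inverse (`quantize=False`) verifies
  the model algebra itself to better than 10⁻⁶. Every capture is
  reproducible bit-for-bit from the scenario seed.

What passing simulator-based tests shows: the implementation inverts its
own forward model, the regression recovers known offsets, and correction
strictly reduces reflectance error whenever a genuine cross-sensor offset
exists. What it does not show: performance under real BRDF, sensor
nonlinearity, moving-cloud transients faster than the mission drift, or
mis-characterised panels — those require field data.

## Problem sizes

Tests and the acceptance script run on small frames (up to 160×120
pixels), 2-capture calibration sets, 107-pair regression samples with 200
replicates — sizes at which every quantity checked is already at its
asymptotic value (the regression slope, for instance, is a function of the
sample size only through its ~n^−1/2 standard error, which at n = 107 is
well inside the tested 2 % band).

## Known limitations

- Georeferencing is pass-through only: rasters are plain multiband TIFFs
  with a JSON metadata tag; no CRS handling, reprojection or mosaicking.
- The packaged regression coefficients are constants of the shipped
  defaults file; refitting from your own missions is supported and
  recommended when the camera or DLS hardware differs.
- EXIF/XMP import from real camera files is out of scope; converting
  vendor metadata into the sidecar schema is the caller's responsibility.
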