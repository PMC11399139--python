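# Methods

`mptet` estimates daily crop evapotranspiration (ET) per pixel from a
Landsat-style optical/thermal scene and scalar overpass meteorology, using a
modified Priestley–Taylor (MPT) formulation driven entirely by remotely
sensed inputs — no ground stations. This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the published formulation is silent or ambiguous.

## Model chain

1. **Surface state.** Broadband albedo is the Tasumi-style weighted sum of
   surface reflectance in OLI bands 2–7 (weights 0.254, 0.149, 0.147,
   0.311, 0.103, 0.036; they sum to 1.000). NDVI comes from bands 4/5, and
   broadband surface emissivity from the logarithmic law
   ε₀ = 1.009 + 0.047 ln NDVI for NDVI > 0.
2. **Net radiation.** Rn = (1 − α) Rs↓ + RL↓ − RL↑ − (1 − ε₀) RL↓, with
   clear-sky shortwave Rs↓ = 1367 · cos θ · d_r · τ_sw from the sun
   elevation in the scene metadata, the Earth–Sun distance factor
   d_r = 1 + 0.033 cos(2π DOY/365), and a broadband transmissivity split
   into beam and diffuse components driven by surface pressure, a
   clearness coefficient K_t and precipitable water
   W = 0.14 e_a P_air + 2.1 (mm). Longwave terms follow Stefan–Boltzmann
   with atmospheric emissivity ε_a = 0.85 (−ln τ_sw)^0.09.
3. **Soil heat flux.** G/Rn = (T_s/α)(0.0038 α + 0.0074 α²)(1 − 0.98 NDVI⁴),
   a midday empirical ratio, clipped to [0, 0.5].
4. **Priestley–Taylor coefficient.** The scene's Ts–Fr scatter (Fr the
   squared rescaled NDVI) forms a triangle. After fitting its dry and wet
   edges, each pixel's coefficient is the two-step linear interpolation
   φ = (Tmax − Ts)/(Tmax − Tmin) · (1.26 − φ_min) + φ_min with
   φ_min = 1.26 Fr, clipped to [0, 1.26].
5. **Fluxes and ET.** LE = φ (Rn − G) Δ/(Δ + γ);
   EF = LE/(Rn − G) = φ Δ/(Δ + γ) identically; instantaneous ET converts
   LE with λ; daily ET uses the modified evaporative-fraction upscaling
   ET_d = α_up · EF · (Rn − G)_d / λ with α_up = 1.1.
6. **Evaluation.** Five statistics on paired observed/estimated ET: R²
   (squared Pearson correlation), RMSE (n denominator), Willmott's
   agreement index d, Nash–Sutcliffe efficiency, and mean bias error.

## Assumptions

- **Flat terrain.** The solar incidence cosine is sin(sun elevation); no
  topographic correction. The method targets flat agricultural districts —
  surface temperature varies with elevation, so mountainous scenes violate
  the triangle's interpretation.
- **Clear sky** at overpass; cloud masking is the user's responsibility
  (AOI mask input).
- **Scene-scalar forcing.** Rs↓ and RL↓ are scalars from single overpass
  meteorology; only surface-dependent fields vary per pixel.
- **Self-calibration.** The triangle edges are fitted per scene from the
  observed scatter, so the scene must span a wide moisture/vegetation range
  (the fit refuses to run below 1000 valid pixels or an Fr span of 0.3).
- **EF constancy.** Daily upscaling assumes the evaporative fraction
  observed at overpass holds through daylight, with the 1.1 coefficient
  compensating the known low bias of plain EF upscaling.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| K_t clearness | 1.0 | – | 1.0 clean air, 0.5 very turbid |
| φ_max | 1.26 | – | well-watered Priestley–Taylor value |
| α_up | 1.1 | – | modified daily upscaling coefficient |
| λ | 2.45 | MJ kg⁻¹ | latent heat of vaporization |
| C_p | 1.013×10⁻³ | MJ kg⁻¹ °C⁻¹ | in γ = C_p P/(ελ) |
| NDVI bounds | 2nd/98th percentile | – | or fixed via config |
| Fr bin width | 0.05 | – | edge-fit binning |
| dry/wet percentile | 99.5 / 0.5 | % | per-bin edge candidates |
| min bin count | 20 | pixels | bins below are skipped |
| edge trim | 2 SD, ≤5 iter | – | drops low dry-edge outliers |
| Tmax clamp | Tmin + 0.5 | K | bounds φ where edges nearly touch |
| latitude | config | deg | daylight length for the half-sine day |

## Numerical and design choices

- **Units in G/Rn.** The surface temperature in the soil-heat-flux ratio is
  taken in °C. In kelvin the ratio exceeds 1 for any realistic scene,
  contradicting the crop-field range (≈0.04–0.18) this ratio is meant to
  reproduce; the underlying empirical fit is a Celsius formulation.
- **Units in ET conversions.** λ enters the instantaneous conversion as
  2.45×10⁶ J kg⁻¹ (so 3600·LE/λ is mm h⁻¹ for LE in W m⁻²), and the daily
  energy total (MJ m⁻² day⁻¹) is divided by λ = 2.45 MJ kg⁻¹ to express
  ET_d as water depth (mm day⁻¹).
- **Water pixels.** The emissivity log-law is undefined for NDVI ≤ 0;
  water-class pixels get the standard broadband water emissivity 0.985, and
  the log-law is floored at 0.9 as NDVI → 0⁺. Water pixels are excluded
  from edge fitting (they would contaminate the wet edge) but still receive
  φ by interpolation.
- **Wet edge is horizontal.** A constant Tmin (median of per-bin low
  percentiles over Fr ≥ 0.5) — the observed wet edge is nearly horizontal;
  an Fr-dependent wet edge is left as a configuration extension.
- **Diffuse-transmissivity branch.** The published piecewise form has a
  0.007 discontinuity at τ_B = 0.15; it is implemented as printed, with the
  ≥ branch at the threshold.
- **Dry-edge fallback.** If the fitted dry slope is positive (no decreasing
  dry edge exists in the scene) the fit falls back to a horizontal dry edge
  at the global dry percentile and flags the scene in the diagnostics.
- **MBE sign.** MBE = mean(observed − predicted), the formula convention; a
  negative MBE therefore indicates model overestimation. Willmott's d uses
  the standard per-term-squared denominator. Both conventions are recorded
  in every report.
- **Daily half-sine.** Instantaneous available energy is assumed to follow
  a half-sine over daylight; the peak is recovered from the overpass value
  and the analytic integral gives (Rn − G)_d, with daily soil heat flux
  taken as zero (daily soil-heat closure). Daylight length comes from the
  sunset-hour-angle formula at the configured latitude.
- **Overpass time.** The MTL scene-center time is used as local solar time;
  for real Landsat products (UTC timestamps) the configuration exposes an
  explicit local-overpass override.
- **Nodata.** NaN marks invalid pixels in memory; a pixel invalid in any
  input band is invalid in every derived field. Files carry a single
  nodata sentinel and a units tag.

## Synthetic scenes: what they do and do not show

The generator emulates a vegetation-gradient cropland scene: per pixel it
draws Fr, draws φ_true uniformly in [1.26 Fr, 1.26] (inside the triangle),
and places Ts by inverting the interpolation against a known dry edge
(default 320 − 15 Fr K) and wet edge (295 K), plus Gaussian temperature
noise (default SD 0.5 K, a plausible compound of sensor noise and sub-pixel
heterogeneity). Reflectance is synthesized by mixing fixed soil/canopy
endmember spectra, with the red/NIR pair constructed so NDVI is exactly
linear in √Fr — the squared-rescaled-NDVI Fr then recovers the generating
Fr exactly when the generator's scaling bounds (0.1, 0.9) are used.

Scene defaults (224×224 ≈ 50k pixels for recovery studies, 200×200 for
range checks) keep every test run in seconds while leaving ≥ 2500 pixels
per Fr bin for the percentile edge candidates.

Passing recovery tests show the edge fit and interpolation are correct and
stable under temperature noise. They do **not** show that real scenes
satisfy the triangle assumptions: real Landsat scenes have atmospheric
residuals, mixed land cover, correlated NDVI/Ts errors, non-uniform Fr
histograms and cloud contamination, none of which the generator emulates.
Validation against lysimeter or flux-tower data remains necessary for any
new region.

## Known limitations

- No LST retrieval: the land-surface-temperature raster is an input.
- No reprojection/resampling; all inputs must be co-registered on one grid.
- No sensible-heat flux; the Priestley–Taylor form avoids it by design.
- Edge fitting needs a heterogeneous scene; small uniform AOIs fail (by
  design, with an instructive error).
- The five validation statistics come without confidence intervals.
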