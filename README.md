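# mptet

Daily crop evapotranspiration (ET) from Landsat-style optical/thermal
scenes with a **modified Priestley–Taylor (MPT)** model — per-pixel net
radiation, soil heat flux, a triangle-interpolated Priestley–Taylor
coefficient, latent heat flux, and daily ET, driven entirely by surface
reflectance, a land-surface-temperature raster and scalar overpass
meteorology. No ground-station observations are required, which makes the
approach practical for irrigation scheduling and water budgeting over
agricultural districts where flux towers and lysimeters are scarce.

## The model

The latent heat flux at overpass is

```
LE = φ · (Rn − G) · Δ / (Δ + γ)
```

where Rn is net radiation, G soil heat flux, Δ the slope of the
saturation-vapour-pressure curve at air temperature, γ the psychrometric
constant, and φ ∈ [0, 1.26] the Priestley–Taylor coefficient. The novelty
of the triangle variant is that φ is determined per pixel from the scene
itself: the scatter of surface temperature Ts against fractional
vegetation cover Fr = ((NDVI − NDVIₘᵢₙ)/(NDVIₘₐₓ − NDVIₘᵢₙ))² forms a
triangle whose upper decreasing boundary (the *dry edge*, maximal water
stress) and lower horizontal boundary (the *wet edge*, unstressed pixels)
are fitted from per-bin temperature percentiles. Each pixel's coefficient
is then the two-step linear interpolation

```
φ = (Tmax(Fr) − Ts) / (Tmax(Fr) − Tmin) · (1.26 − 1.26·Fr) + 1.26·Fr
```

so φ = 1.26 on the wet edge and φ = 0 at the dry bare-soil corner. Daily
ET follows from evaporative-fraction upscaling, ET_d = 1.1 · EF ·
(Rn − G)_d / λ, with the daily available energy integrated from a
half-sine diurnal course. Model skill is scored with R², RMSE, Willmott's
agreement index d, Nash–Sutcliffe efficiency and mean bias error.

See `docs/methods.md` for the full chain, assumptions, parameters and
design decisions.

## Worked example

Generate a synthetic vegetation-gradient scene with a known triangle
(dry edge 320 − 15·Fr K, wet edge 295 K, 0.5 K temperature noise), run
the full pipeline on it, and validate a paired ET series:

```python
from mptet import RunConfig, run_scene
from mptet.synthetic import (TriangleParams, generate_triangle_scene,
                             write_scene_to_dir, generate_validation_pairs)
from mptet.evaluation import evaluate

scene, truth = generate_triangle_scene(
    TriangleParams(n_rows=200, n_cols=200, ts_noise_sd_K=0.5, seed=42))
paths = write_scene_to_dir(scene, "scene")

config = RunConfig(
    band_paths={b: f"scene/band{b}.tif" for b in range(2, 8)},
    mtl_path="scene/MTL.txt", lst_path="scene/lst.tif",
    ta_K=298.0, pair_kPa=100.0, ea_kPa=1.5, latitude_deg=29.0,
    ndvi_min=0.1, ndvi_max=0.9, outdir="out")
manifest = run_scene(config)
print(manifest["edges"])

report = evaluate(generate_validation_pairs(8, bias=0.1, noise_sd=0.3, seed=7))
print(report)
```

prints

```
{'dry_intercept': 320.1977258467709, 'dry_slope': -14.696324084289206,
 't_min': 294.62442825317385}
n    = 8
R2   = 0.9456
RMSE = 0.2181 mm/day
d    = 0.9823
NSME = 0.9229
MBE  = -0.0658 mm/day
```

The fitted edges sit within a fraction of a kelvin of the generating
truth (320 K intercept, −15 K/Fr slope, 295 K wet edge), and the
validation report recovers the injected +0.1 mm/day bias as a negative
MBE (the convention is observed − predicted) broadened by the 0.3 mm/day
noise. `out/` now holds GeoTIFFs for albedo, NDVI, Rn, G, φ, LE, EF,
instantaneous and daily ET, the fitted edge model as JSON, a per-scene
summary CSV (date, mean, max, SD, pixel count of daily ET), and a
manifest with parameters and checksums.

The same workflow is available from the shell:

```sh
mptet synth --outdir scene --seed 42
mptet run config.json
mptet validate pairs.csv
```

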