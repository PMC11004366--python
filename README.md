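# grazecap

Grassland carrying capacity and grass–livestock balance analysis from
monthly remote-sensing inputs, for quantitative rangeland ecologists and
remote-sensing analysts working in arid and semi-arid grasslands.

The package implements the full chain used in regional stocking-rate
assessments:

1. **Cross-sensor NDVI fusion.** A long legacy NDVI record *G* is calibrated
   against a modern sensor *V* per pixel over their overlap window,
   `G = a + b·V + ε` (ordinary least squares, all overlap months pooled),
   and legacy months are mapped onto the modern scale to form one seamless
   monthly series.
2. **CASA NPP.** Net primary productivity from the light-use-efficiency
   model `NPP(x,t) = APAR(x,t) · ε(x,t)`, with `APAR = SOL·FPAR·0.5` (FPAR a
   linear NDVI ramp between per-grassland-type envelopes) and
   `ε = Tε1·Tε2·Wε·ε_max` (temperature and water stress scalars).
3. **Forage yield and carrying capacity.** Aboveground allocation
   `fANPP = 0.171 + 0.0129·MAT` (clamped to [0,1]), dry-forage yield
   `F = NPP·fANPP / 0.47` (g/m², ×10 = kg/hm²), and the theoretical stocking
   rate `CC = AGB·Gᵢ / (L·D)` in sheep units per hectare, with utilization
   rate `Gᵢ` per grassland type, intake `L = 1.8 kg/d` and grazing days `D`,
   aggregated to monthly, seasonal and annual windows.
4. **Grass–livestock balance.** County herd inventories are converted to
   sheep units (cattle 5, horse 5, mule 5, donkey 2.5, camel 8, sheep 1.2,
   goat 0.8 SU/head), compared with zonal theoretical capacity through
   `Ip = (A − CA)/CA · 100%`, and graded I–IV (not / slight / moderate /
   severe overload at 0 / 25 / 50 %).
5. **Trend diagnostics.** Pixel-wise Theil–Sen slope, tie-corrected
   Mann–Kendall test, four-way trend classes (SD/NSD/NSI/SI), coefficient of
   variation with stability classes, and rescaled-range Hurst persistence.
6. **Driver attribution.** Geographical-detector factor `q = 1 − SSW/SST`
   and pairwise interaction detection with the standard five interaction
   categories.

Because the real satellite, climate and yearbook inputs of such studies are
rarely redistributable, the package ships a first-class synthetic scene
generator (`grazecap.synthetic_scene`) that produces NDVI/climate/driver
rasters and herd tables with known ground truth — known sensor calibration,
known driver effect sizes, known overload grades — so the entire pipeline is
testable end to end.

## Worked example

Run the whole pipeline on a small synthetic scene (32×32 pixels, monthly
2000–2009, modern sensor from 2005, 4 counties):

```python
from grazecap import RunConfig, SceneConfig, run_pipeline

cfg = RunConfig(
    scene=SceneConfig(grid_rows=32, grid_cols=32, years=(2000, 2009),
                      modern_start_year=2005, n_counties=4),
    seed=42,
    out_dir="example_run",
)
manifest = run_pipeline(cfg)
```

The manifest this prints (seed 42) summarises each stage:

```
fuse     mean_slope 0.9002, mean_intercept 0.0499, mean_r2 0.9842
npp      mean_annual_npp_gC_m2 175.3
capacity mean_annual_cc_su_hm2 1.209, peak_month 2009-07
balance  mean_ip_weighted_pct -0.094, n_overloaded_last_year 2
detect   ranking precipitation > elevation > som > temperature > ... > aspect
         q: precipitation 0.472, elevation 0.214, som 0.141, temperature 0.102
```

Reading these numbers: the fusion stage recovered the scene's true sensor
calibration (a = 0.05, b = 0.9) from the noisy overlap; annual NPP
(~175 gC/m²/yr) is in the arid-steppe range; the carrying-capacity field
peaks in July as mid-latitude grassland phenology dictates; the region is on
average almost exactly in grass–livestock balance (Ip ≈ −0.1%) with two of
four counties overloaded in the final year; and the factor detector
recovers the generator's designed driver ordering, with annual precipitation
the dominant control of stocking capacity.

The same stages are available as a CLI:

```bash
grazecap simulate --out scene --seed 1
grazecap fuse --long scene/ndvi_a.tif --modern scene/ndvi_b.tif --out fused
grazecap run --config run.yaml --out results --seed 1
```

## Layout

- `src/grazecap/synthetic_scene.py` — scene generator with ground truth
- `src/grazecap/ndvi_fusion.py` — per-pixel OLS calibration and harmonization
- `src/grazecap/casa_npp.py` — CASA light-use-efficiency model
- `src/grazecap/forage_capacity.py` — fANPP partitioning, yield, stocking rate
- `src/grazecap/livestock_balance.py` — sheep units, balance index, grading
- `src/grazecap/trend_stack.py` — Theil–Sen, Mann–Kendall, CV, Hurst
- `src/grazecap/geodetector.py` — factor/interaction q statistics
- `src/grazecap/pipeline.py`, `cli.py`, `io.py` — orchestration and I/O
- `docs/methods.md` — the model, parameter and design documentation
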