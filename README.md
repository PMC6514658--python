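# rgbpheno

Plot-level RGB high-throughput plant phenotyping from consumer cameras.

Field breeding programs need cheap, fast proxies for crop performance —
especially for maize under low soil nitrogen, where leaf chlorosis and
reduced canopy cover are the visible symptoms of stress. A plain RGB
camera, held over the canopy or flown on a UAV, captures both. This
package turns such photographs into plot-level vegetation indices, runs
the camera quality checks that should precede scientific use of a
consumer camera, and carries the analysis through to trial level:
genotype yield comparisons across nitrogen treatments and multivariate
yield models. It is written for crop physiologists and breeders running
two-treatment field trials, and for anyone building an RGB phenotyping
pipeline who wants the index math and its QA in testable library form.

## The indices

Hue-threshold indices operate in HSI space, where hue is an angle with
red at 0°, green at 120°, blue at 240°:

- **GA** (green area): fraction of pixels with hue in [60°, 180°) —
  vegetation cover including yellowish green;
- **GGA** (greener green area): the stricter [80°, 180°), excluding
  yellow-green stressed tissue;
- **CSI** (crop senescence index): `CSI = 100 · (GA − GGA) / GA`.

Broadband indices treat the camera channels as reflectance bands
centered near 670/550/480 nm (reflectance = DN/255):

- **TGI** = `−0.5 [190 (R670 − R550) − 120 (R670 − R480)]`, a triangle-area
  chlorophyll proxy (190 = λ1 − λ3, 120 = λ1 − λ2);
- **NGRDI** = `(R550 − R670) / (R550 + R670)`.

Normalized-difference chroma indices use the CIE 1976 color spaces,
which separate lightness from chroma and are therefore robust to
illumination and vignetting:

- **NDLab** = `((1 − a*) − b*) / ((1 − a*) + b*) + 1`
- **NDLuv** = `((1 − u*) − v*) / ((1 − u*) + v*) + 1`

evaluated per pixel and averaged (a plot-mean variant is a flag). Green
vegetation (negative a*/u*) scores high; red-brown soil and yellow
chlorosis (positive b*/v*) score low. See `docs/methods.md` for the
formula's edge cases, which are implemented literally and documented.

Trial level: grain yield `GY = X · 10 / 5.25` (Mg/ha from kg/plot),
grain yield loss index `GYLI = (GY_OP − GY_LOW)/GY_OP · 100`, visual
senescence `SEN = (YC + DC)/(YC + DC + GC)`, rank quartiles (HY/MHY/
MLY/LY) per treatment with cross-treatment overlap, Pearson correlation
tables, one-way ANOVA with Fisher LSD letters, and forward/backward
stepwise AIC multiple regression with a "simplified formula" reduction.

## Worked example

```python
from rgbpheno import SceneSpec, render_scene, summarize_plot

img, masks = render_scene(SceneSpec(veg_fraction=0.4, chlorotic_share=0.25, seed=7))
rec = summarize_plot(img, "plot001")
for k in ("ga", "gga", "csi", "hue_mean", "ndlab", "ndluv", "tgi", "ngrdi"):
    print(f"{k:10s} {getattr(rec, k):8.3f}")
```

prints

```
ga            0.400
gga           0.300
csi          25.000
hue_mean     60.368
ndlab         0.118
ndluv        -2.232
tgi          16.476
ngrdi         0.029
```

The synthetic scene was built with 40 % vegetation cover of which a
quarter is chlorotic, and the indices recover exactly that: GA = 0.40,
GGA = 0.30 (the non-chlorotic share), CSI = 25 % (the chlorotic share of
the vegetation). The remaining rows are the plot means that feed the
correlation and regression layers.

The same flows are available from a shell:

```sh
rgbpheno synth scene --out-prefix scene --veg-fraction 0.4 --seed 7
rgbpheno index scene.png --out indices.csv
rgbpheno synth trial --out-prefix trial --seed 1
rgbpheno agronomy --trial trial.csv --out summary.csv
rgbpheno run --config pipeline.yml     # crop -> index -> join -> correlate -> model
```

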