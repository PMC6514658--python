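# Methods

## Color model

All conversions assume 8-bit sRGB input (IEC 61966-2-1 gamma decoding,
D65 white point, 2° observer) with no chromatic adaptation or ICC
profile handling. Consumer cameras emit sRGB JPEGs by default, and the
analysis this toolkit implements uses camera values uncalibrated — the
calibration check exists to verify that this is acceptable, not to
correct the data (an opt-in linear correction is provided).

HSI is hand-rolled: hue by the standard hexcone formula (red 0°, green
120°, blue 240°), intensity = mean(R, G, B)/255 and saturation
= 1 − min/intensity (the classic HSI definitions; note HSV's S and V
differ). Intensity and CIELab lightness L* are reported as distinct plot
variables. Achromatic pixels (R = G = B) carry an explicit undefined-hue
flag; they count in GA/GGA denominators — they are scene pixels, e.g.
specular soil — but can never count as green. CIELab/CIELuv conversions
delegate to scikit-image, which uses the classic published constants
(sRGB matrix, D65 tristimulus 0.95047/1/1.08883, and the rounded CIE
junction constants 0.008856, 7.787, 903.3); the test suite checks them
against an independently coded per-pixel implementation of the CIE
formulas to 1e-6 on 1000 random pixels.

## Index definitions and numerical choices

- Hue windows are closed-left/open-right, [60°, 180°) for GA and
  [80°, 180°) for GGA. The endpoint convention is a measure-zero choice
  made for determinism.
- CSI = 100 (GA − GGA)/GA is **missing** (NaN) when GA = 0: zero
  vegetation is not zero senescence. GGA > GA is an invariant violation
  and raises.
- TGI and NGRDI use channel means scaled to [0, 1] as band reflectances
  (no radiometric calibration). The TGI wavelength coefficients follow
  from the triangle-area formula at band centers 670/550/480 nm:
  λ1 − λ3 = 190, λ1 − λ2 = 120.
- NDLab/NDLuv are evaluated per pixel and averaged over pixels whose
  denominator magnitude exceeds ε = 1e-6 (all-excluded → missing). A
  plot-mean variant (`per_pixel=False`) evaluates the formula at the
  plot-mean chroma instead; per-pixel is the default because that is how
  the hue-threshold indices are defined. **Edge cases, implemented
  literally rather than "fixed":** at a* = b* = 0 the formula evaluates
  to 2, outside its nominal [−1, 1] range, and the denominator
  (1 − a*) + b* changes sign for strongly red, weakly yellow colors
  (u* > v* + 1 in Luv), where the index becomes large and unstable.
  Real soils can approach this line in CIELuv; users comparing NDLuv
  across very red soils should prefer the plot-mean variant or inspect
  the excluded-pixel count.
- The plot hue mean is circular (mean resultant direction), since an
  arithmetic mean of angles is wrong across the 0/360° wrap.

## Camera QA

The ColorChecker check regresses each measured channel (R, G, B, L, a*,
b*) on the 24 reference chips by OLS and flags channels with R² < 0.80.
Chip patches are summarized by their median, robust to specular rim
pixels. The bundled reference table is **synthetic/nominal**: the
classic 24-patch sRGB coordinates in wide circulation, with Lab derived
from those sRGB values under D65 by this package (the file is named
`colorchecker24_synthetic.csv` accordingly). Because the check is an
affine regression, substituting any published edition of the chart via
CSV changes intercepts/slopes but not the structure of the report.

Vignetting is assessed on the central row and column transects of R, G,
B, hue, a*, b*, restricted to sunlit bare-soil pixels. The soil filter —
hue outside [60°, 180°), saturation > 0.1, intensity > 0.2 — is the
complement of the vegetation hue window with shadow and achromatic
pixels removed; all three thresholds are configurable. Brightness-only
distortion (lens falloff) bows the RGB transects while leaving the
lightness-separated chroma axes comparatively flat; the test suite
quantifies this as mean RGB transect variance ≥ 10× the worst chroma
transect variance on cos⁴-distorted synthetic scenes.

## Agronomy

GY = X·10/area with area defaulting to 5.25 m² (0.75 m row spacing × 2
rows × 3.5 m harvested length); grain weight is assumed already
standardized for moisture upstream. GYLI is undefined (NaN, with a
warning) when GY at OP is not positive; negative GYLI (LOW outyielding
OP) is retained. ASI = SD − AD, negatives retained. Genotype yield for
quartiling is the replicate mean; quartiles are assigned in descending
yield with ties broken by genotype name so labels are invariant to row
order. Overlap percentages are rounded to the nearest integer percent
(7/16 → 44 %).

## Statistical layer

Correlations are Pearson with two-sided p and the conventional stars.
ANOVA letters use Fisher's LSD at α = 0.05 on the pooled MSE, displayed
via the insert-and-absorb compact-letter algorithm on the
descending-mean order. Stepwise selection is AIC-guided OLS (Gaussian
likelihood, k = 2 — the same ranking as R's `stepAIC`, which differs
only by an additive constant); directions forward, backward, or both,
with steps taken only on strict AIC decrease, making selection
deterministic for a fixed table. Complete-case rows only; singular
candidate fits are skipped. The "simplified formula" reduction
iteratively removes, first, the weaker member (by marginal |r| to the
response) of any predictor pair with pairwise |r| ≥ 0.7 (configurable —
the collinearity cut is a judgment call with no canonical value), then
the least significant predictor with p ≥ α, refitting after each drop.
Simplified-model R² can never exceed the full model's (nested OLS).

## Synthetic data

The scene generator emulates the three optical classes of a young maize
trial photographed from above: red-brown sunlit soil (hue ≈ 36°), green
canopy (hue ≈ 113°) and yellow-green chlorotic tissue (hue ≈ 65°),
placed as seeded elliptical blobs so that coverage is spatially coherent
rather than salt-and-pepper (the last blob is trimmed so class pixel
counts hit the requested fractions exactly, making mask-count oracles
exact). Texture is multiplicative brightness jitter applied in encoded
DN space: a common per-pixel gain preserves hexcone hue *exactly*, which
guarantees the invariant that every mask pixel's hue lies in its class's
programmed band — the design reason jitter is not additive channel
noise. The default soil color is also chosen away from the NDLuv
singular line discussed above so the chroma indices are well-defined on
soil. Vignetting is a cos⁴ radial falloff applied multiplicatively in
linear RGB before re-encoding, since falloff physically acts on sensor
irradiance.

What the generator does **not** emulate: leaf-scale texture and
specular highlights, mixed soil/vegetation boundary pixels at coarse
GSD, shadows, atmospheric/illumination drift between frames, and real
soil color diversity. Passing index-recovery tests on these scenes
therefore validates the index math and thresholds, not segmentation
robustness on real canopies.

The trial simulator draws genotype yield effects from a correlated
bivariate normal across treatments (LOW mean 2.93, SD 0.55; OP mean
9.62, SD 1.10 Mg/ha at genotype level, replicate noise 0.25/0.45),
spanning roughly 1.5–4.4 Mg/ha under LOW and 6.7–12.3 under OP — the
magnitudes of a managed low-N maize trial with 64 genotypes × 3
replicates. Covariates are generated with programmed genotype-level
correlations to yield (defaults: ASI −0.53 and AD −0.46 under LOW,
weakly positive under OP; PH +0.19; SEN −0.21; NDVI +0.38; SPAD
+0.54/+0.51), and the canopy-class columns are constructed so that
SEN = (YC + DC)/(YC + DC + GC) holds by construction. The generative
parameters are returned for recovery tests.

## Problem sizes

The test suite and acceptance script use 120×90 to 201×151-pixel scenes
(100 seeds for index recovery), 1000 random pixels for the conversion
oracle, and 100 seeds of n = 192 rows × 10 predictors for stepwise
selection consistency — sizes at which every statistical check is
well-resolved while the full suite runs in well under a minute.

## Known limitations

- Only axis-aligned rectangular plot ROIs; polygon masks are a noted
  extension.
- No photogrammetric mosaicking, georeferencing, or automatic plot
  detection: the orthomosaic and ROI table are inputs.
- No NDVI from RGB (no NIR band); field-sensor NDVI/SPAD enter only as
  table columns.
- No 16-bit or raw pipelines; images with alpha channels are rejected
  rather than flattened.
- No moisture correction of grain weight and no spatial field-trial
  adjustment (BLUPs, heritability) — out of scope.
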