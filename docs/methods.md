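# Methods

`olivetray` estimates the ripeness degree of a harvested olive lot from a
single photograph of the tray it was collected into. This note documents the
model and procedure the package implements, the parameters that matter, what
the synthetic scene generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## The pipeline

A tray photograph passes through four stages:

1. **Colorimetric calibration.** A 24-patch color checker placed in the scene
   (on the first acquisition, and periodically thereafter) anchors a warp of
   the RGB cube that undoes the scene's global color cast. The warp is a
   thin-plate-spline-style interpolant in 3-D color space,

   `f(p) = b + M p + Σᵢ wᵢ φ(‖p − cᵢ‖)`,

   fitted so that every measured patch color `cᵢ` maps exactly onto its known
   reference value, with side conditions `Σᵢ wᵢ = 0` and `Σᵢ wᵢ cᵢᵀ = 0` that
   force any affine cast into the affine part `(M, b)`. One fitted warp is
   applied per pixel to the whole batch of images acquired under the same
   conditions.
2. **RGBHS features.** The calibrated image is converted to HSV; hue and
   saturation are appended to R, G, B; each of the five channels is median
   filtered. Hue and saturation carry the peel-color signal that separates
   black, purple and green olives; the value channel mostly tracks
   illumination and is deliberately left out.
3. **k-NN pixel segmentation.** Every pixel's 5-vector is classified into one
   of 7 scene classes — background, yellow tray, red tray, leaves, black /
   purple / green olives — by majority vote among its k = 5 nearest training
   vectors under plain Euclidean distance. The training set holds 1025
   labeled vectors, each the mean of a 10×10-pixel annotated patch
   (138 background, 141 yellow tray, 121 red tray, 235 leaves, 138 black,
   131 purple, 121 green olives).
4. **Ripeness statistic.** The per-tray ripe fraction is
   `100 · n(black) / [n(black) + n(green) + n(purple)]` over olive pixels.
   Purple (turning) olives sit in the denominator only. A ternary mask
   (white = ripe, gray = unripe green, black = everything else) visualizes
   the segmentation.

Independently of the imaging pipeline, the classical Jaén maturity index is
provided: with 100 fruits binned into color categories 0 (deep green) … 7
(fully black) and per-category counts A…H,
`MI = (A·0 + B·1 + … + H·7)/100 ∈ [0, 7]`.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `kernel_name` | `"linear"` (φ(r) = r) | natural biharmonic kernel in 3-D; `"thin_plate"` (φ(r) = r² log r) is the classical 2-D formula carried over verbatim, selectable for comparison |
| `regularization` λ | 0 | exact interpolation of the 24 control pairs; λ > 0 trades exactness for smoothness with noisy patch measurements |
| `sampling_fraction` | 0.5 | central fraction of each patch ROI averaged, keeping clear of patch-edge bleed |
| median `window` | 5 px | small enough to preserve olive boundaries at both the native (5184×3888) and the scaled-down synthetic scale; applied to all five channels (an `"hs"`-only mode exists) |
| `patch_size` | 10 px | training patches; for even sizes the annotated center sits at the top-left of the central 2×2 |
| `k` | 5 | neighbors in the vote |
| channel weights | all 1 | no standardization of the 5 axes; a weight vector is exposed for experimentation |

## Numerical and convention choices

- **Color scale.** Images are floats in [0, 1] in memory; 8-bit quantization
  happens only on write. Warp outputs are clamped to [0, 1] and the clamp
  count is logged.
- **Warp fitting.** The (n+4)×(n+4) saddle-point system is solved densely;
  a condition number above 10¹² (e.g. near-duplicate measured colors under
  the smooth thin-plate kernel) raises an error suggesting λ > 0. Duplicate
  measured patch colors (pairwise distance ≤ 10⁻⁹) are rejected outright,
  naming the colliding patches.
- **Hue conventions.** H lives in [0, 1); achromatic pixels get H = 0. Hue is
  treated as a *linear* coordinate in filtering and in the Euclidean metric —
  a faithful naive treatment; circular statistics are intentionally not the
  default.
- **k-NN tie rules** (needed because k = 5 over 7 classes can tie): neighbor
  sets at equal boundary distance prefer the lower class code; vote ties go
  to the class whose nearest member among the tied classes is closest. Both
  rules are deterministic and make the result invariant to training-set
  order; the implementation (a stable distance sort over a class-sorted
  training array, with an argpartition fast path) is tested for exact
  agreement against an exhaustive brute-force sort oracle, including
  engineered exact ties.
- **Degenerate inputs.** A segmentation with zero olive pixels yields a
  flagged *undefined* ripe fraction, never a silent 0%. Maturity-index counts
  that do not sum to 100 are normalized by their actual sum with a warning.
  Report sorting is stable, so tied trays keep their input order.

## The synthetic scene generator

Real validation data (66 tray images and two operators' manual counts for 10
of them) is not publicly deposited, so the package ships a generator whose
scenes carry exact per-pixel ground truth: a tray rectangle (yellow or red)
on a background, non-overlapping olive ellipses with aspect ratio drawn from
[0.7, 1.0] (olive-shape variability is a documented error source and is
exposed as a stress parameter), elongated leaf ellipses, i.i.d. Gaussian
pixel noise (σ = 0.012 ≈ 3/255, a realistic sensor-noise scale), an optional
rendered checker, and parameterized affine+gamma color casts standing in for
illumination changes. Default class colors are mutually separated by ≥ 0.25
in RGB norm so that, at default noise, residual pipeline error is
attributable to the pipeline itself.

The default scene is 480×640 with ~40 olives of 12–20 px radius — roughly
1/8 of the native acquisition scale; multi-tray experiments use 320×416
scenes to keep whole-suite runtimes in minutes. A single scene has one tray
color, so full 7-class training sets are assembled from a yellow-tray scene
plus a red-tray companion.

**Leaf-confusion stress mode.** Field trays contain leaves whose color can
approach unripe-olive green; green olives then leak into the leaf class,
shrinking the olive denominator and biasing the ripe fraction upward. The
generator reproduces this by placing the leaf color a configurable distance
from the green-olive color. The stress default displaces it by 0.004 in RGB
norm — comparable to the median-filtered noise scale, so the two class
distributions genuinely overlap and the denser leaf training (235 vs 121
patches in the full profile) absorbs green-olive pixels volumetrically. At
larger separations the confusion is confined to ellipse boundaries and its
sign depends on scene geometry rather than on the mechanism of interest.

**What passing synthetic tests does not show.** The generator has no
shadows, specular glare, droplets, camera optics, olive surface texture or
gloss, partial occlusion between fruits, or spatially correlated noise; its
class palettes are flat colors. Synthetic recovery therefore demonstrates
the correctness and internal consistency of the algorithms — not
field-grade accuracy, which on real data was limited by exactly the
unmodeled factors above (operator-visible olive aspect variability, leaf
contamination).

## Known limitations

- The checker's position must be supplied (explicit ROIs, or 4 chart corners
  expanded to a 4×6 grid); there is no automatic chart detection.
- Frames that still contain the checker should not be scored for ripeness:
  the chart's dark frame and near-black patches classify as black olives and
  inflate the ripe fraction. The intended workflow fits the warp on the
  checker shot and scores the checker-free tray photos that follow it.
- One fitted warp is reused verbatim across a batch; no interpolation
  between successive checker shots.
- Per-olive instance detection and counting are out of scope; the statistic
  is pixel-areal, so large olives weigh more than small ones.
- The leaf-share normalization sketched qualitatively in the source method
  ("divide by the maximum percentage") is under-specified and deliberately
  not implemented; the leaf pixel share is reported instead.
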