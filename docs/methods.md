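# Methods

## Problem and model

`naevoscreen` ranks H&E photomicrographs of naevoid lesions for pathologist
review. The underlying model is a *trainable pixel segmentation*: a
two-class random forest over a hand-crafted multi-scale filter bank, the
approach popularized by interactive segmentation tools in microscopy. The
two classes are C₁ (regular clusters) and C₂ (possible anomalous
clusters); the forest is trained on sparsely annotated pixels and applied
to every pixel of a case image. The scalar the triage rule consumes is the
*equivalent-area percentage*: the fraction of image area whose C₂ vote
fraction exceeds the red threshold, converted to physical units via
scale-bar calibration.

Assumptions worth stating explicitly:

* anomalous regions are distinguishable from regular tissue by local color
  and multi-scale texture (density/darkness of nuclei), which is what the
  filter bank can see; architectural cues beyond ~2·16 px are invisible;
* the printed scale bar is a solid horizontal run of near-constant color,
  longer than any other such run in the image;
* area is an adequate risk proxy — the method counts suspicious pixels, it
  does not delineate or classify lesions.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| min/max sigma | 1 / 16 | px | powers-of-two ladder {1,2,4,8,16} |
| membrane patch / thickness | 19 / 1 | px | 30 rotations of 6° |
| forest size | 200 | trees | √d features per split, min leaf 1 |
| red threshold | 0.38 | vote fraction | strict `>`; overridable per run |
| triage threshold | 12 | % of image area | strict `>`; boundary not suspected |
| scale bar | 500 | µm | per-image calibration, never global |
| max labeled px / class / image | 2000 | px | training subsample cap |

The red and triage thresholds are frozen defaults of the screening
protocol, exposed as flags because an appropriate value depends on the
image filtering threshold and on the lesion population being screened.

## Numerical choices

* **Sigma ladder.** The ladder is `min_sigma · 2^k ≤ max_sigma`. Only the
  endpoints are protocol inputs; the geometric spacing is the
  trainable-segmentation convention.
* **Grayscale.** Filters operate on the ITU-R 601 luma; raw R/G/B are kept
  as channels instead of filtering per channel, keeping the stack at 40
  channels.
* **Hessian.** Central differences of the Gaussian-smoothed image, not
  sampled Gaussian-derivative kernels: the discrete sampled kernels do not
  annihilate/reproduce polynomials exactly (on z = x² they return a
  curvature that drifts from 2 by O(10⁻²)), while smoothing followed by
  `np.gradient` is exact on quadratics away from borders. Channels are the
  two eigenvalues per scale, larger first.
* **Membrane kernels.** Binary line kernels are normalized to unit sum so
  all rotations respond identically to a constant image and the std
  projection vanishes there; without normalization the pixel count of the
  rasterized line varies with angle.
* **Borders.** Reflect padding everywhere.
* **Probabilities.** `p_C2` is the exact fraction of trees voting C₂.
  Trees are exported to flat arrays after fitting and all prediction goes
  through one vectorized array-walk, so freshly trained and JSON-reloaded
  models are bit-identical. Vote counting (rather than averaging leaf
  class frequencies) makes the brute-force per-tree oracle exact; with
  unlimited depth and min leaf 1 the two coincide anyway.
* **Tie-breaks.** Strict inequalities at both thresholds (a pixel at
  exactly 0.38 is not red; a case at exactly 12% is not suspected);
  worklist ties break lexicographically by case id.
* **Determinism.** Labeled pixels are extracted from masks in row-major
  order, all RNGs are explicit `numpy.random.Generator`s, and case reports
  carry no timestamp by default, so batch outputs are byte-identical
  across reruns.
* **Degenerate inputs.** Undefined precision/recall are NaN with an
  explicit flag; a missing scale bar raises a dedicated error and can be
  bypassed with a manual µm/px; a failing case is recorded without
  aborting its batch.

## Synthetic data

The generator emulates the acquisition geometry of the screening protocol
(1920 × 1088 px, 2.5 µm/px, 500 µm bar → 200 px) and the cytologic cues the
classifier is supposed to exploit: eosin-pink textured background
(230, 180, 200) with Gaussian noise (SD 8), purple elliptical nuclei
(95, 65, 145; radius 3–7 µm; 1500/mm²), and anomalous regions — smoothed
random fields thresholded at the quantile matching the requested area
fraction — carrying 3× nucleus density, darker hyperchromatic color
(55, 30, 95), polygonal (angulated) outlines and a mild 15% regional
darkening. Cohorts draw benign fractions from U(0.01, 0.05) and
malignant-like fractions from U(0.15, 0.30), deliberately straddling the
12% triage threshold.

What the fixtures do **not** emulate: stain variability and stain overlap,
tissue architecture (rete ridges, maturation gradients), focus/compression
artifacts, immunohistochemistry appearance. Passing the end-to-end tests
therefore shows the pipeline recovers planted area fractions under the
stated noise model — it says nothing about sensitivity or specificity on
real slides, which would require annotated clinical material.

## Problem sizes

End-to-end validation runs at 480 × 272 px (same 2.5 µm/px), training on
two annotated fixtures (≤ 1500 labeled pixels per class per image) and
screening ten held-out cases; unit tests use 256 × 160 fixtures. These
sizes keep the full suite and the acceptance script at a few minutes on a
single core while leaving every stage — bar detection, 40-channel stacks,
200-tree forests, calibration, triage — identical to full-resolution
operation, which is a pure scale-up.

## Open design points and limitations

* Whether the original protocol fits one model across all training cases
  or one per image is unspecified; `ScreeningPipeline.fit` accepts any set
  of annotated images, so both protocols are expressible, and neither is
  claimed canonical.
* The percentage is computed as equivalent/total × 100. The protocol's
  verbal description of step 8 inverts the ratio, but a total/equivalent
  ratio exceeds 1 and could not sit under a 12% threshold; the inverted
  reading is the only internally consistent one and is adopted as a
  documented interpretation.
* The scale-bar detector assumes defaults (black, tolerance 40, min run
  50 px) that are guesses about unstated annotation conventions; they are
  configurable and a manual µm/px override exists.
* Precision/recall are computed over labeled pixels only; no attempt is
  made to reproduce learning-curve behavior over annotation effort, whose
  abscissa is tool-defined and not reproducible here.
* The red count is taken from the probability map, never re-counted from
  the rendered red-on-black overlay, avoiding colormap round-trip error.
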