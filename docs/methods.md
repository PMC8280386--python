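# Methods

## The segmentation system

`lungseg` implements a three-stage segmentation of the lung region in axial
thoracic CT slices in which each stage of the classical
preprocess / process / postprocess decomposition is carried out by a small
neural network:

1. **Preprocessing.** The slice is Otsu-binarized and a three-stage
   convolutional classifier (CNN-1: 3×3 convolutions with 8, 16 and 32
   filters, each stage conv → ReLU → batch norm → 2×2 max pool, softmax
   head) decides whether the slice contains lung at all; slices without
   lung short-circuit to an all-zero mask. Surviving slices pass a quality
   gate: a no-reference quality score is computed and slices scoring below
   τ₁ = 0.9 are contrast-enhanced (tuning parameter β = 4) before further
   processing.
2. **Processing.** A U-net (UNET-1; two 3×3/64-filter no-padding
   convolutions with two 2×2 pools for ×4 down-sampling, two stride-2
   3×3/64-filter transposed convolutions for ×4 up-sampling, 1×1 class
   head, symmetric zero-padding restoring the input frame) converts the
   slice into a label image whose brightest class is the body. The
   candidate lung region is the set of dark cavities enclosed by the body:
   pixels background in the body mask but foreground after hole filling,
   minus components smaller than 0.1% of the image area.
3. **Postprocessing.** The contour statistic τ₂ = A₂/A₁ (hole-filled area
   over Canny edge-pixel count; τ₂ = 0 when there are no edges) measures
   contour closure: filled, smoothly bounded regions score high. Candidates
   with τ₂ below the threshold (default 12) are routed to a second U-net
   (UNET-2) that predicts the closed lung contour; the predicted contour is
   used to bridge gaps (below). The region is then hole-filled, split into
   8-connected components, and each component is kept only if a second
   classifier (CNN-2) recognizes it as lung.

Two ablation modes mirror the studied system configurations:
`without_cnns` removes both classifiers (no slice gating, no component
filtering) while keeping the U-nets; `without_enhancement` removes only the
quality-gate evaluation/enhancement.

## Synthetic thorax phantom

Real thoracic CT with expert masks is not shipped with the package; a
parametric phantom provides unlimited slices with exact ground truth.
Intensities are normalized to [0,1] with nominal tissue levels background
0.05, lungs 0.15, table 0.55, pathology 0.65, body 0.75 — chosen so Otsu
thresholding separates air from tissue, as it does in real CT. A slice is a
bright body ellipse on dark background containing two dark lung ellipses
with jittered axes and low-frequency boundary perturbation (smooth but
non-analytic contours). A thin bright arc cradles the body from below; its
tips end inside the body so the dark sliver between arc and body becomes an
enclosed cavity after hole filling — the canonical false-positive component
the component classifier must reject (in real scans: air trapped between
patient and table, bowel gas, etc.). Pathology (ground-glass/fibrosis-like)
is modeled as bright blobs centered on the lung contour, overwriting a
`pathology_severity` fraction of the contour: this locally erases the
lung/body intensity edge, the failure mode contour refinement targets. The
ground-truth mask keeps the full anatomical lung including the diseased
tissue. Contrast gain rescales intensities about mid-gray; Gaussian noise
(default σ = 0.02) is added last.

The phantom is anchored to the classical stage: at severity 0 and noise 0
the pure classical pipeline (Otsu → hole filling → candidate extraction)
recovers the ground truth with Dice ≥ 0.98, and mean classical Dice
decreases monotonically with severity. What the phantom does **not**
emulate: anatomical texture, airways/vessels, lobe structure, 3-D slice
continuity, scanner-specific noise spectra, or real pathology morphology.
Passing tests therefore demonstrate that the *system logic* (gating,
candidate extraction, refinement routing, false-positive filtering) works
and trains as described — not clinical-grade accuracy on patient data.

## Training data factories

The factories replace interactive visual-inspection steps of a manual
workflow with ground-truth-driven rules so sets can be rebuilt
deterministically:

- **CNN-1 set** — Otsu-binarized slices labeled by the generator's
  `contains_lung` flag.
- **CNN-2 set** — slices are 2-class k-means clustered; cavity components
  of the bright class are rendered one-per-image full-frame (position and
  size cues preserved) and labeled lung iff their Dice overlap with a
  ground-truth lung component is ≥ 0.5.
- **UNET-1 set** — five configurations: (1) ground-truth mask → copy;
  (2) Otsu binary → copy; (3) largest Otsu component (holes unfilled) →
  copy; (4) grayscale → 2-class k-means labels; (5) grayscale → 3-class
  k-means labels. Class ids are intensity-ordered. Images pass the same
  quality gate the pipeline applies at inference, so the network trains on
  the domain it will be fed.
- **UNET-2 set** — input: the dark lung tissue inside the ground-truth mask
  (mask pixels at or below the slice-level Otsu threshold), which exhibits
  pathology-induced contour gaps; label: the Canny edge image of the mask,
  always a closed curve. Edge labels are extracted at the network's working
  resolution because a one-pixel curve does not survive label resampling.

## Networks, optimization, numerics

The layer stack (`lungseg.nn`) is a self-contained numpy implementation —
im2col convolutions backed by BLAS matmuls, transposed convolutions as the
exact adjoint of the strided convolution, max pooling with first-argmax
routing, per-channel batch norm with running statistics — which keeps the
package dependency-free beyond the scientific Python stack and makes
training bit-reproducible on one CPU. All parameters are float32; every
source of randomness (He initialization, shuffling, splits) derives from
the training-config seed.

Optimization is minibatch SGD with momentum 0.9 under softmax cross-entropy
(per image for classifiers, per pixel for U-nets). The full-scale defaults
(initial learning rate 0.001, 100 epochs, validation every 30 iterations,
minibatches of 32) are kept as the `TrainConfig` defaults; desk-scale runs
use the documented overrides learning rate 0.1, minibatch 16 and ≈150
iterations, at which the binary identity-style configurations converge in a
few dozen iterations. Edge-label training uses inverse-class-frequency loss
weighting: at ≈2% edge prevalence an unweighted loss drives the network to
the all-background solution.

U-nets are fully convolutional, so inference runs at the slice's native
resolution even though training patches are 64×64; this keeps boundary
placement pixel-accurate (candidate Dice ≈ 0.94–0.96 versus ≈ 0.90–0.93
through a resample-to-64 round trip). The classifiers have a fixed dense
head and therefore resize inputs (bilinear, with a logged warning).
UNET-1 networks trained on binary configurations (1–3) are fed the Otsu
binarization of the gated slice at inference; grayscale configurations
(4–5) are fed the gated slice itself. The training input domain is recorded
in the model checkpoint and the pipeline dispatches on it.

## Contour refinement

UNET-2 predicts the closed lung contour from the (binary) candidate image
at its 64×64 working resolution. The refinement composes as a
*union-closure*: the predicted edge is dilated by 1 px into a ring,
up-sampled onto the slice, united with the candidate and hole-filled; the
filled region is eroded by round(2.5 × scale) pixels (scale = slice size /
working size) to remove the ring's outward overhang, and the final region
is the union of that interior with the original candidate. Refinement can
therefore only bridge contour gaps, never carve away candidate pixels.
Replacing the candidate wholesale with the filled predicted contour was
measured consistently worse at every severity on development data and was
rejected. If no edge pixels are predicted the candidate passes unchanged.

A note on τ₂ scale: τ₂ grows linearly with image size (area/perimeter), so
at 128 px phantom scale healthy lungs score τ₂ ≈ 7–9 and essentially all
candidates route through refinement under the default threshold of 12,
which was calibrated on full-size CT. The union-closure design keeps this
near-lossless on already-good candidates; the threshold remains
configurable (`PipelineConfig.tau2_threshold`).

## Quality gate surrogates

The no-reference quality metric and the contrast-enhancement algorithm used
by the original gate are published elsewhere and are represented here by
fully documented surrogates behind a two-function interface
(`quality.backend` style plugging): the score is the RMS contrast of the
hole-filled Otsu body region divided by a calibration constant 0.30
(clipped to [0,1]); the calibration makes a nominal-contrast phantom slice
score ≈ 0.95 (above τ₁ = 0.9) while a gain-0.5 slice scores ≈ 0.5, so both
gate branches are exercised. Enhancement is the rank-preserving sigmoid
`expit(β·(x − median)/σ)` centered on the body median with scale σ = body
intensity std; as β → 0 it tends to a flat 0.5 image.

One interaction worth knowing: phantom pathology (0.65) lies below the body
median, so the sigmoid maps it dark and enhanced slices arrive at the
candidate stage with partially *healed* contours. The refinement ablation
is therefore evaluated at nominal contrast gain 1.0, where slices pass the
gate unenhanced and pathology genuinely breaks the candidate contour —
otherwise the comparison would measure the enhancement stage, not the
refinement stage.

## Desk-scale study conditions

The benchmark the tests and the acceptance script run: 500 training and 100
test slices at 128×128 px, 80% containing lungs, pathology severity uniform
on [0, 0.3], contrast gain uniform on [0.7, 1.0], noise σ = 0.02. CNN-1,
CNN-2 and UNET-2 are configuration-independent and trained once; UNET-1 is
trained per configuration (2 and 5 in the benchmark). The refinement
ablation uses 40 extra severity-0.3, gain-1.0 lung slices. These sizes are
the package's desk-scale choices; the factories accept arbitrary slice
collections for larger studies.

## Degenerate inputs and tie-breaks

Constant images raise a degenerate-input error in Otsu and score 0 quality;
k-means requires at least k distinct intensities. Otsu ties break toward
the lower cut; binarization is strict (`intensity > threshold`). Connected
components use 8-connectivity with raster-order labeling; hole filling
floods the background 4-connected (the complementary pairing). τ₂ with no
edge pixels is defined as 0 (worst quality — always refine). Dice of two
empty masks is 1 by convention. Components touching the image border are
classified by CNN-2 like any other.

## Known limitations

- Phantom realism is geometric, not anatomical; results do not transfer to
  clinical data without retraining on real slices.
- The U-nets have no skip connections (by design: two convolutions down,
  two transposed convolutions up), which caps boundary accuracy at roughly
  one pixel at working resolution.
- The quality gate surrogates share only the interface and gate semantics
  with the originally referenced metric/enhancement algorithms.
- The default τ₂ threshold of 12 is calibrated for full-size CT; at small
  phantom scales it routes nearly everything to refinement.
- Per-slice 2-D processing only; no volumetric consistency.
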