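# Methods

`fundoprep` implements a preprocessing, evaluation, ensembling, and
explanation pipeline for multi-label screening of chronic ocular diseases
(COD) in color fundus photographs. Eight binary flags are predicted per
patient, in the fixed order **N** (normal), **D** (diabetic retinopathy),
**G** (glaucoma), **C** (cataract), **A** (age-related macular
degeneration), **H** (hypertensive retinopathy), **M** (pathological
myopia), **O** (other abnormality). This note records the models and
procedures, the parameters that matter, the numerical choices, and what the
synthetic test bed does and does not establish.

## Region-of-interest segmentation

A fundus photograph is a bright, roughly circular retina on a near-black
camera background. Training on the full frame wastes capacity on
background; the cropper isolates the disc.

Candidate circles are detected on a gradient edge map (Sobel magnitude
thresholded at 50) with a circular Hough transform at an accumulator
resolution equal to the image resolution. Peaks are kept when their centers
are at least 20 px apart and their accumulator support reaches 30 votes.
The radius search spans `floor(min(H, W)/4)` to `max(H, W)`; since no
circle with radius beyond half the image diagonal can receive votes, the
search is capped there internally (the configured upper bound is retained
in the parameter object). Candidates are ranked by accumulator score, with
ties broken toward the larger radius — when in doubt, prefer not losing
foreground.

The fundus circle is the first candidate whose bounding box, expanded by a
5-row/5-column margin, contains every pixel brighter than
`nonzero_threshold` (default 0, i.e. strictly nonzero; real JPEG
backgrounds need a small positive value because of compression noise —
tests on synthetic PNGs use 0). If no candidate passes, the one excluding
the fewest foreground pixels is used, and if its box still leaks foreground
the cropper falls back to the tight bounding box of all foreground pixels
(the whole frame for an empty image); the `CropBox.method` flag records
which path produced the box. Boxes are half-open, 0-based, clamped to the
frame, and the crop is resized to 256×256 *after* cropping so lesion scale
is preserved relative to the disc.

An Otsu largest-component baseline (`otsu_contour_crop`) is included for
comparison. A global Otsu threshold on a dark image can land inside the
retina and clip the dim part of the disc; the test suite constructs exactly
this failure (half-dim disc) and verifies that the Hough crop keeps the
full disc where the baseline loses it.

Grayscale for detection is standard luma (0.299 R + 0.587 G + 0.114 B);
the sources describing the procedure are silent on the channel choice.

## Image enhancement

All operators preserve image dimensions and are deterministic.

**CLAHE.** Per-tile histogram equalization with a clip limit. For each
tile of a 5×5 grid the intensity histogram `P_n` is clipped at
`clip_limit × tile_pixels / L` (contrast factor 2, `L = 256` levels),
the clipped excess is redistributed uniformly over all bins, and the
mapping is `I_eq = floor((L−1) · CDF(I))`. Pixel outputs bilinearly blend
the four surrounding tile mappings, the standard interpolation that removes
tile seams; with a single tile the mapping is applied directly, which is
the configuration the hand-computed oracle test uses. The tile reading of
"5×5" is a 5×5 *grid* (roughly 51×51-px tiles at 256×256); 5×5-pixel
tiles would make equalization degenerate. For RGB input the transform is
applied to each channel independently; the alternative of equalizing a
luminance channel only is not implemented. CLAHE requires integer input
because the histogram is indexed by intensity.

**Gaussian unsharp blend.** `I_gs = α·I + β·(G_σ ∗ I) + γ` with α = 4,
β = −4, σ = 10, γ = 128, clipped to [0, 255]. Because α + β = 0 the
operator is a pure band-pass: any constant image maps exactly to γ = 128.
That closed form is used as a test invariant, and it constrains the
implementation: smoothing uses reflective borders and a kernel half-width
of 4σ so that convolution of a constant is exact at the frame edge.

**Multiscale retinex.** `I_msr = Σ_n W_n (log(I+ε) − log(G_σn ∗ I + ε))`
over scales (5, 35, 150) with equal weights 1/3 and ε = 1 (8-bit
convention, avoids log 0). The raw map of a constant image is identically
zero, and the map is linear in the weights — both are asserted as
properties. The raw map is min-max rescaled to [0, 255] over the whole
array (jointly across channels, preserving inter-channel relations); a
degenerate range maps to all zeros rather than dividing by zero. MSR is
applied per RGB channel by default (`MsrConfig.per_channel`); whether a
luminance-only variant is preferable is an open choice the config exposes.

**Variants.** `apply_variant` composes cropping with the operators into
the named pipelines: `original`, `cropped`, `green`, `green_clahe`,
`green_gaussian`, `rgb_clahe`, `rgb_gaussian`, `msr`, `vessel_seg`,
`vessel_inpaint`.

## Vessel operations

`segment_vessels` accepts any backend mapping an RGB raster to a same-size
response map, so a trained neural segmenter can be plugged in unchanged.
The built-in `naive_backend` is a classical stand-in — CLAHE on the green
plane, black top-hat with a radius-4 disk, Otsu threshold over the
foreground — adequate for synthetic phantoms (recall ≥ 0.5 on vessels of
width ≥ 2 px is asserted) but not a clinical vessel segmenter.

`clean_mask` applies the two-stage cleanup in the stated order: pixel
intensities below 20 are zeroed first, then any 8-connected component with
fewer than 100 pixels is zeroed — a 100-pixel component survives (the
"less than" boundary is tested on 99- and 100-pixel components).
Connectivity 8 is the default because thin diagonal vessels disconnect
under 4-connectivity; both are supported, and small-mask behaviour is
verified against a brute-force flood-fill oracle. The size filter operates
on the thresholded intensity mask, so a sub-threshold gap can split a
component before the size rule is applied.

`inpaint_vessels` replaces masked pixels with a biharmonic diffusion fill
from the surrounding background (neural generative inpainting is out of
scope; the contract accepts any fill through the image/mask interface).
Unmasked pixels are returned bit-identical; a mask covering the whole image
is rejected. On phantoms the generator renders a vessel-free twin of every
image, and inpainting is verified to move masked pixels toward that twin.

## Labels

Per-eye diagnostic keyword strings are mapped to label bits by ordered,
case-insensitive substring matching over comma-separated phrases
("hypertensive" is matched before "retinopathy" so hypertensive retinopathy
does not collapse into DR). Unmatched phrases map to the catch-all **O**
class, or raise in strict mode. The patient label is the bitwise union of
the two eye labels, except that **N** survives only when *both* eyes read
normal-only. When a declared label is available the union is verified
against it; mismatches are logged and reported, never silently overwritten.

Patient-level scores aggregate the two eyes by label-wise maximum; a
missing eye passes the present eye through, so single-visit patients need
no special casing. DR grade lists binarize as 0 → normal, 1–4 → abnormal,
5 (ungradable) → excluded, and the screening score from an 8-class
prediction is `1 − score(N)`.

## Augmentation

Batch-level augmentation emits, per image: the original, a horizontal
flip, a vertical flip, and a rotation by an angle drawn uniformly from
±30° (bilinear interpolation, zero fill — the fundus background is black).
Expansion is 4× with all flags on. The expansion is offline (the expanded
list is materialized); the same functions can be called per epoch for
on-the-fly use. All randomness flows from one seed: the same seed yields
byte-identical batches. Rotation and flips do not change any disease flag,
so labels are replicated, never recomputed.

## Model accounting, loss, metrics

**Parameter accounting.** Eleven ImageNet backbones are supported
(SqueezeNet v1.1, MobileNetv2, Inception v1 = GoogLeNet without auxiliary
heads, DenseNet121, EfficientNet-B3, ResNeXt50-32x4d, ResNet50,
Inception v3, EfficientNet-B7, WideResNet50-2, VGG16). `model_zoo`
enumerates every trainable layer of each backbone analytically
(convolution = Cin/groups · Cout · kH · kW + bias, batch-norm = 2C,
dense = D·K + K), and `build_classifier` swaps the final 1000-way dense
layer for an `n_classes`-way head whose weights are initialized from a
shared `head_seed`, the same initialization protocol for every
architecture. Counts satisfy the head-swap identity
`total = published_1000 − (d·1000 + 1000) + (d·n + n)` with `d` the
penultimate width, which the tests check against the published 1000-class
totals — a genuinely independent route, since the structural enumeration
never uses those totals. Two variant choices matter and were fixed by this
identity: Inception v1 counts without its auxiliary classifiers, while
Inception v3 keeps its auxiliary branch *including* the auxiliary 1000-way
classifier (only the main dense layer is swapped); GoogLeNet's "5×5"
branch uses 3×3 kernels, as in the reference implementation.

**Loss.** The multi-label one-versus-all max-entropy loss,
`−(1/C) Σ_i [ y_i log σ(ŷ_i) + (1−y_i) log(1−σ(ŷ_i)) ]`, averaged over the
batch, computed via `log σ(x) = −log(1+e^{−x})` in log-sum-exp form so it
is stable for |ŷ| well beyond 100. At ŷ = 0 every term is log 2 regardless
of the target, a closed form the tests pin down.

**Metrics.** Per-class confusion counts give macro precision and recall
(mean of per-class ratios); F1 is the harmonic mean of the *macro*
precision and recall, matching the formula order of the evaluation
protocol, with the per-label-then-averaged F1 reported alongside.
Degenerate 0/0 ratios are defined as 0 with a warning. Kappa is the
unweighted mean over the 8 labels of per-label Cohen's kappa from the 2×2
agreement table; when chance agreement is 1 (constant marginals), kappa is
defined as 1 for perfect agreement and 0 otherwise. AUC is the macro mean
of per-label trapezoidal ROC areas (via scikit-learn), skipping labels
with a single observed class. A per-decision "challenge granularity" score
is also provided: the fraction of record×label cells answered correctly,
under which exactly one correct decision out of 500×8 scores
1/4000 = 0.00025.

**Desk-scale training.** `fit` trains `TinyFundusClassifier`, a one-layer
logistic model on pooled image features (8×8 mean-pooled green plane,
channel means/SDs, bright/dark-pixel fractions, 4×4 dark-structure density
grid), by mini-batch gradient descent on the loss above. The per-epoch
trace records batch losses *before* each update, so a zero learning rate
provably yields a constant trace. This model exists to exercise the
training loop, loss, metrics and aggregation end to end at desk scale on a
single CPU; it is not a CNN and makes no accuracy claims beyond beating
the all-Normal baseline on synthetic data.

## Ensembling and explanation

`majority_vote` takes exactly three aligned binary label matrices (three
architectures, or three preprocessing variants) and emits 1 per cell when
at least two members agree; three members means no ties, and the
equivalence with the sum ≥ 2 formulation is asserted on random matrices.
Voting operates on binarized labels (threshold 0.5, inclusive); score
averaging is available as an option, and odd member counts other than 3
sit behind an explicit flag.

Grad-CAM weights each activation channel of the last convolutional layer
by the spatial mean of its gradient map, sums, and rectifies negatives to
zero (rectification before normalization, per the original method). The
map is min-max normalized per image to [0, 255] — hence invariant to
positive rescaling of the raw map, and a constant raw map (e.g. all-zero
gradients) maps to all zeros — then bilinearly resized to the image and
thresholded at 100 to form the mask. Contours of the mask are drawn on a
copy of the image, green when the prediction score is ≥ 0.5 (0.5 itself is
green) and red otherwise; only contour pixels differ from the input.
Activations and gradients are plain arrays, so the module is testable
without a trained network and usable with hooks from any framework.

## Synthetic phantoms

The generator renders what the pipeline's contracts assume: a bright
retinal disc (possibly off-center or clipped by up to 30% of its area) on
a strictly-dark background (< 20 outside the disc plus a one-pixel
anti-alias ring — optional truncated background noise stays below 20, so
the "nonzero outside" crop rule and the intensity-20 mask threshold are
both exercised with known truth), dark random-walk vessel polylines of
width 1–3 px confined to the disc (giving connected components of
controllable size for the 100-px filter), a bright nerve head, a lateral
illumination gradient, and per-class lesion motifs: dark hemorrhage-like
and bright exudate-like dots (D), drusen-like blobs (A), an enlarged
bright cup (G), global haze (C), widened extra vessels (H), a rim
crescent (M), a gray patch (O). Ground truth per image: exact disc circle,
vessel mask, lesion coordinates, label vector, and a vessel-free twin for
inpainting evaluation. Disc radii are drawn from 0.33–0.46 of the frame
side — the default frame is 256×256, matching the pipeline's working
resolution. Everything is byte-deterministic under a seed.

`generate_dataset` writes left/right PNG pairs per patient with an
ODIR-style CSV manifest (per-eye keyword phrases from a fixed
one-phrase-per-class vocabulary, 8-bit final label). Diseased patients get
a healthy left eye 30% of the time so the two-eye union logic is actually
exercised; patient conditions are drawn i.i.d. from the requested class
mix.

What passing on phantoms shows: the geometry, thresholds, order of
operations, determinism, and score arithmetic of every stage are correct,
and the full pipeline runs end to end. What it does not show: performance
on real fundus photographs — phantoms have no camera vignetting, JPEG
noise, anatomical variation, or realistic lesion morphology, and the
desk-scale classifier is not a CNN. Real-data benchmark results are out of
scope here.

## Problem sizes and defaults used in the checks

The self-checks use 50 randomized phantoms for disc-recovery (pass
criterion: IoU ≥ 0.90 against the true disc box in ≥ 45, margin rule in
100% of non-fallback crops), 300 synthetic patients (600 eyes, 80/20
patient-level split, 4× augmentation, 2 training epochs) for the
end-to-end smoke run, and 200×8 random matrices for metric-oracle
equivalence — sizes chosen so the whole suite runs in a few minutes on one
CPU while keeping the binomial/recovery margins statistically comfortable.
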