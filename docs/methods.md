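# Methods

## Problem setting

Intravascular ultrasound (IVUS) produces cross-sectional grayscale images
of coronary arteries from a catheter withdrawn at constant speed, with
frames extracted at 0.5-mm intervals along the pullback. Reading these
frames requires recognizing five pixel classes — background, lumen,
media+plaque, calcification, stent — and two clinically actionable flags:
a *narrowed lumen* (cross-sectional area < 4 mm², associated with elevated
risk of major adverse cardiac events) and *severe calcification* (a
calcium arc occupying more than two of the four 90° quadrants around the
vessel center, which changes the interventional strategy).

This package implements that reading pipeline end to end on synthetic
data: a phantom generator with analytic ground truth, a five-class U-Net,
the clinical derivations, and the evaluation statistics. Clinical IVUS
datasets of this kind are essentially never public, so the phantom
generator is a first-class, tested component: it is what makes every
downstream stage verifiable.

## Phantom model

A frame is an ellipse-in-ellipse geometry rasterized on a square grid:

- **Lumen**: an ellipse with semi-axes `(a, b)` mm, rotation, and a center
  that wanders slightly around the image center. The analytic lumen area
  is `π·a·b`.
- **Media+plaque**: the annulus between the lumen ellipse and an outer
  (adventitial) ellipse of semi-axes `(a+w, b+w)` sharing center and
  rotation, with wall thickness `w ∈ [0.5, 0.9]` mm.
- **Calcification**: an angular arc × radial band starting just above the
  lumen border (offset 0.02–0.08 mm, thickness 0.15–0.30 mm), carved out
  of the annulus so the five classes partition the image.
- **Stent**: 6–10 bright struts on a ring just outside the lumen
  (`max(a,b) + 0.06` mm), stamped last so struts may overlap the lumen
  border, as they do clinically.

B-mode rendering assigns each class an echogenicity (anechoic lumen 0.06,
media 0.50, calcification leading edge 0.95, struts 1.0, perivascular
background 0.20), adds a bright catheter ring at the image center,
attenuates everything radially outward of calcification and struts to a
configurable residual (default 0.15) to model the acoustic shadow, and
optionally draws a bright guide-wire ray (a known clinical failure mode
for segmentation). The deterministic map is blurred with a σ = 0.7 px
Gaussian point-spread function, then multiplied by a speckle field:
Rayleigh-distributed noise (the envelope statistics of fully developed
ultrasound speckle), smoothed with a σ = 0.8 px Gaussian for a finite
correlation length and normalized to unit mean, with a contrast knob
`speckle_scale` (default 0.35; 0 yields the deterministic map exactly).

### Pullback correlation and dataset composition

A patient is a trajectory of geometries, not independent frames. All
continuous parameters follow Gaussian random walks with reflecting bounds,
Gaussian-smoothed targets, and a hard per-frame step clamp of 0.08 mm on
each lumen semi-axis. Lesion attributes occupy contiguous frame runs whose
lengths are drawn `Binomial(frames, fraction)`, so dataset-level
prevalences converge to the configured fractions while neighboring frames
remain nearly identical — the structure that makes patient-level data
splitting matter.

Default composition mirrors the clinical material this generator
emulates: 59.1% of frames calcified, 12.3% stented, 28.7% of calcified
frames severe, 24 patients × 156 frames (≈ 3 700 frames). The narrowed
fraction is not derivable from published composition counts; the default
0.30 was chosen once as a realistic prevalence for a complex-lesion
cohort and gives both classes enough support for the image-level
classification statistics.

Normal lumen mean radii are drawn from [1.20, 1.50] mm (areas 4.5–7.1 mm²)
and narrowed-run radii from [0.70, 1.00] mm (1.5–3.1 mm²), so frames are
unambiguous on either side of the 4-mm² threshold except during smooth
transitions — which is exactly where a strict threshold should be
exercised.

### Well-posedness of the arc ground truth

The analytic quadrant count must be recoverable from rasterized pixels,
whose angles about the lumen pixel-centroid carry ~1° of jitter. The
generator therefore keeps every arc endpoint at least 3° away from
quadrant boundaries (pulling endpoints inward when they fall closer): a
quadrant is either overlapped by ≥ 3° or cleared by ≥ 3°, never grazed.
Severe runs draw arc extents from [200°, 320°] (always > 2 quadrants);
mild runs draw [20°, 160°] anchored inside two adjacent quadrants.

Resolution defaults: 256×256 at 0.02 mm/px (5.12-mm field of view,
plausible for a high-frequency catheter); the scaled-down training runs
use 64×64 at 0.08 mm/px, preserving the field of view. Published IVUS
export resolutions and calibrations vary by console, so pixel spacing is
an explicit configurable everywhere.

## Mask codec

Masks are RGB PNGs with one flat color per class: black background, green
lumen `(0,255,0)`, red media+plaque `(255,0,0)`, orange calcification
`(255,165,0)`, blue stent `(0,0,255)`. Clinical labeling conventions name
the colors but not RGB values; pure primaries plus web-orange make
nearest-color decoding unambiguous. Decoding assigns each pixel the
nearest palette color under max-channel distance and rejects pixels
farther than a tolerance (default 10) from every entry, so antialiased
third-party masks decode while genuinely foreign colors raise an error
listing offending coordinates.

## Network

The U-Net has `depth` encoder levels (default 3, counting the
bottleneck): per level two 3×3 convolutions (stride 1, 'same' padding)
each followed by ReLU and dropout (rate 0.1), 2×2 max-pooling between
levels, filter counts doubling from `base_filters` (default 16); the
decoder mirrors with 2×2 nearest-neighbor upsampling and skip
concatenation, and a 1×1 convolution produces five logits per pixel.
Training uses categorical cross-entropy, Adam at learning rate 0.001,
batch size 2, 20% frame-wise validation from the training patients, and
augmentation by horizontal/vertical flips and rotations.

The implementation is pure NumPy with hand-derived backpropagation:
convolutions via im2col (the data gradient is itself a convolution with
the flipped, channel-transposed kernel, avoiding a scatter), float32
throughout, He initialization. Correctness is guarded by a
finite-difference gradient check and an analytic parameter-count oracle;
everything is bit-deterministic under a fixed seed, which no GPU framework
guarantees.

Numerical/design choices worth stating:

- **Rotations are restricted to 90° multiples** and applied as pixel
  permutations, so label masks stay exact and per-class pixel counts are
  invariants rather than approximations.
- **Argmax ties break toward the lower class index** (background first) —
  a documented convention, exercised only by degenerate logits.
- **Epoch budget**: defaults `max_epochs=8`, early stopping with patience
  10 on validation loss, best-validation weights restored. The
  scaled-down runs in tests and the acceptance script use 5 epochs, after
  which the validation loss has flattened at this problem size.
- **Class weighting** is available in `TrainConfig` (the stent class is
  extremely pixel-imbalanced) but off by default.

## Clinical derivations

- **Lumen area** = lumen-pixel count × spacing² (mm²); **narrowed** is a
  strict `area < 4.0`.
- **Calcification arc**: angles of calcification pixels about the lumen
  pixel-centroid are collected into 1° bins; the arc is the count of
  occupied bins (summing occupied angle across disjoint deposits, not a
  convex span). Gaps of up to 4° are closed (circularly) before counting,
  absorbing rasterization dropouts of thin bands at small radii; deposits
  separated by more than that remain distinct. The quadrant count is the
  number of fixed 90° sectors (anchored at the +x axis) containing an
  occupied bin; **severe** means more than two quadrants. An alternative
  `arc > 180°` rule is available behind `severe_rule="arc180"`. "More
  than two quadrants" has no canonical anchoring in the literature; fixed
  sectors about the lumen centroid is this package's operationalization.
- **Struts**: connected components of the stent class (8-connectivity)
  with at least `min_pixels` (default 3, suppressing single-pixel noise),
  reported by centroid. **Strut recall** matches predictions to truth
  one-to-one within a tolerance (default 5 px), maximizing the number of
  matched pairs by optimal assignment (Hungarian algorithm; among maximum
  matchings the smallest total distance is chosen). Optimal rather than
  greedy matching: greedy closest-pair can sacrifice a feasible match and
  understate recall. Frames with no true struts return recall 1.0 and are
  excluded from stented-frame aggregates.

## Evaluation statistics

Per-class one-vs-rest confusion counts give IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN), accuracy, recall and precision; 0/0 ratios are
defined as 1.0 (class absent from both masks). Means over classes are
computed in two explicitly tagged modes — `pooled` (counts summed over
all images first) and `macro_per_image` (per-image metrics averaged over
images where the class is present in truth) — because the two can differ
substantially and published mean IoUs are rarely unambiguous about which
was used. Classes absent from every truth mask are excluded from means so
stent-free evaluation sets are not inflated by convention ones.

Lumen-area agreement uses Spearman's tie-corrected rank correlation; its
p-value is exact (full permutation enumeration) for n ≤ 8 and the
t-approximation above. Exact enumeration at n = 9–10 would cost minutes
for a quantity nobody reports at that n; the t-approximation is already
accurate there. R² is the squared Pearson correlation of the two area
lists, i.e. the coefficient of determination of the simple regression.

## What the phantoms do and do not show

Passing tests on phantoms demonstrates that the pipeline's mechanics are
correct — the generator's ground truth is recoverable, the network can
learn the mapping, the metrics and flags are computed exactly — and that
patient-level evaluation generalizes across synthetic patients. Phantoms
are far easier than clinical frames: no bifurcations, side branches,
thrombus, dissection flaps, plaque heterogeneity, ring-down or
reverberation artifacts, and speckle is stationary. Absolute metric
values on phantoms (e.g. lumen IoU ≈ 0.98 at desk scale) therefore do not
predict clinical performance; the stent class, however, already shows the
clinically reported failure mode (near-zero IoU under extreme pixel
imbalance) even here.

## Problem sizes

Desk-scale defaults were chosen so the full loop runs on one CPU: the
scaled-down learning checks train on 20 patients × 30 frames at 64×64
(depth 3, base 16, 5 epochs, ≈ 2 minutes each), and geometry-recovery
checks use 200 phantoms at 256×256. The generator's composition defaults
stay at the clinical-scale values regardless of problem size.
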