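# Methods

## The classification model

A plasma frame is reduced to a block-mean RGB vector: the region crop is
partitioned into `n_w × n_h` equal rectangles (`n_w` divisions across the
width, `n_h` down the height; every grid used in practice divides the
crop exactly), each block contributes its per-channel arithmetic mean,
and the triplets are concatenated row-major. Means are computed and kept
in double precision; rounding happens only when a vector is painted back
into a block-averaged image. The vector length is `3·n_w·n_h` — from 3
(whole-image mean color) up to three times the pixel count (a flattening
of the image itself).

Training is a single averaging pass: each category's centroid is the
element-wise mean of its training vectors. Classification assigns a test
vector to the centroid with maximum cosine similarity
`S_c = x·y/(‖x‖‖y‖)`. Because features are nonnegative, `S_c` lies in
`[0, 1]`; on plasma images it crowds so close to 1 that the min–max map
`S_norm = (S_c − S_min)/(1 − S_min)` — with `S_min` the minimum over the
*entire* test's similarity matrix, not per row — is applied for display.
`S_norm` is affine and order-preserving, so it never changes a decision.

Model assumptions worth stating explicitly:

* cosine similarity is invariant to positive scaling of either vector, so
  the classifier is blind to global brightness (exposure) differences and
  to any information carried only by the *magnitude* of the mean color;
* it is equivariant under any fixed permutation of vector entries, so the
  block traversal order (row-major here, frozen for file compatibility)
  is immaterial to accuracy;
* averages are taken on stored (gamma-encoded) channel values, the
  literal reading of "mean RGB"; no linearization is attempted.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| grid `n_w × n_h` | per sweep | block divisions across width / down height |
| strict divisibility | on | grids must divide the crop; permissive mode truncates remainder rows/columns |
| region offsets | centered defaults | crop positions in the source frame (px); sizes are fixed by the protocol |
| heatmap floor | 0.90 | lower display limit when plotting `S_norm`; display-only |

Ties in the argmax (measure-zero on real data) break toward the first
label in canonical category order — analyte column order `C, B, A, BC,
AC, AB, He`, then ascending pressure — using exact float comparison with
no epsilon. Accuracy is reported both as an exact fraction and rounded to
one decimal percent.

## The synthetic generator

`plasmavoc.synthetic` renders what the classifier assumes about a frame,
not the plasma physics: a dark background at a constant black level
(default 10/255, matching the nonzero black level of camera frames and
keeping additive noise clip-free), one or two vertical Gaussian-profile
light columns under a vertical Gaussian envelope (the plasma body), a
per-analyte emission hue scaled by that intensity field, a deterministic
additive hue shift per pressure step (default `(+7, +2, −6)` channel
units per step above 17 Psi), a Gaussian-blurred, intensity-scaled copy
of the column profile near the bottom of the frame (the reflection band,
default scale 0.15), and i.i.d. Gaussian pixel noise (default σ = 2
channel units) clipped to `[0, 255]` and quantized to 8 bits. Every image
is a pure function of (config, label, seed); datasets regenerate
byte-for-byte.

The default canvas is 216×270 (width × height), an exact 1/5 of the
full-scale region-1 crop, so the published grid ratios all have exact
small-integer analogues; the analogue crops are the full canvas
(region 1), a 70×63 window on the plasma (region 2 — chosen so the 10×9
grid divides it, since the exact 1/5 scale of 360×324 is not integer),
and a 108×80 bottom band (region 3).

Two study conditions are built in:

* **Mean-color-matched pairs.** The analyte pairs (C, BC) and (A, AB)
  share hue, column width and total luminous flux but differ in column
  count and placement. Their noiseless whole-image mean colors are then
  *identical* (same direction and magnitude), so the 1×1 grid cannot
  separate a pair member from its partner even in principle — the
  decision reduces to noise — while already the coarsest segmented grid
  (4×5) sees block-mass differences of tens of channel units against a
  per-block noise of ~0.04. Column centers were placed so the pair
  members' block-mass distributions differ at 4×5 (a single column at
  0.42/0.58 of the width versus double columns at 0.33/0.67 and
  0.35/0.70). This makes "segmentation rescues classification" a
  structural property of the condition rather than a lucky draw: with 8
  matched pairs across 4 pressures, the chance that a whole-image
  classifier gets all of them right is about `(1/4)^8 ≈ 10^-5`, and
  every whole-image error lands on the matched partner at the same
  pressure. All other hue pairs are separated by ≥ 40 channel units
  (validated at construction; violations are rejected naming the pair).
* **Helium baseline.** A single lilac analyte whose hue drifts toward
  white with pressure, 6 training + 1 test replicate per pressure, and a
  10× smaller noise scale (σ = 0.2). Within-category cosine spread
  (max − mean similarity to the own centroid) scales roughly with σ², so
  the helium condition's spread sits about two orders of magnitude below
  the VOC condition's — the tight-baseline regime in which nearest-
  centroid classification is always perfect.

What the generator does *not* emulate: plasma emission physics, shape
changes within a category, temporal injection transients, camera optics
(vignetting, chromatic response, JPEG artifacts), or inter-replicate
exposure drift. Passing tests therefore demonstrate that the pipeline
recovers the designed color/structure contrasts under pixel noise; they
do not certify accuracy on real camera frames, which the optional
full-scale schedule (`table2_sweep`) addresses against the deposited
dataset.

## Numerical choices

* Cosine values are clamped to `[−1, 1]` to absorb last-bit float
  overshoot on self-similarity; all other arithmetic is plain float64.
* Block means use numpy's pairwise summation; agreement with a naive
  double-loop is asserted to 1e-9 in the tests.
* `reconstruct` rounds means half-to-even via `np.rint`; at one pixel per
  block the means are integers and the reconstruction is exact.
* Degenerate inputs are rejected rather than coerced: zero vectors (no
  direction), empty blocks, empty categories, all-ones similarity
  matrices (normalization would divide by zero), out-of-bounds crops,
  non-dividing grids in strict mode.
* Generator seeding uses `numpy.random.SeedSequence.spawn` per category
  and replicate in a fixed order, so datasets are reproducible and
  per-image streams independent.

## Problem sizes

The shipped tests and the acceptance script run entirely on the
desk-scale canvas: 24 categories × 6 replicates (144 images of 216×270)
for the VOC condition and 4 × 7 for helium, with grids up to one block
per pixel on the region analogues. Full-scale geometry (1080×1350 and
540×400 frames) is exercised for feature extraction, where it costs
milliseconds; full-scale classification sweeps are left to the optional
real-data path.

## Known limitations

* Region offsets within the original frame are configuration, not
  estimates; no plasma-localization step is provided.
* A test image whose true category is absent from training is classified
  into the closest present category; there is no open-set rejection.
* The permissive (truncating) grid mode discards remainder pixels at the
  right/bottom edges; use it only when a non-dividing grid is truly
  needed.
* Timing columns in sweep outputs are wall-clock measurements for
  orientation only; they are hardware-dependent and never asserted on.
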