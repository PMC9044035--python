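# Methods

## Radiometric calibration

Raw frames are converted to reflectance with per-pixel, per-band white
and dark references: `R = (raw − dark) / (white − dark)`.  The
denominator is clamped at 10⁻⁶ and pixels at or below the clamp are
returned in a flag mask rather than raising — dead sensor elements are
a data-quality property of a frame, not a caller error.  Output is
clipped to [0, 1.5] on the fraction scale: specular highlights can
legitimately exceed the white panel, but unbounded values would poison
downstream statistics.  Reflectance lives on the fraction scale
throughout the package; percent is an I/O presentation.  The 0.3 leaf
threshold below only makes sense on the fraction scale.

## Wavelength grid

The target sensor's 147-band layout (468–898 nm) is slightly
non-uniform and its exact grid lives in the camera's calibration file.
`hsileaf.wavelengths` reconstructs it by monotone PCHIP interpolation
through 30 publicly documented (band, wavelength) anchor pairs.  One
documented pair (band 32 at 557.84 nm) is inconsistent with band 30 at
569.27 nm — a wavelength table must be strictly increasing — and is
treated as a transcription slip and excluded.  Real data always
prefers the wavelength table in its own header; the reconstructed grid
exists so synthetic cubes and index-based selections report physically
sensible wavelengths.

## Leaf masking and tiling

Tiles are cut row-major from the top-left with residual margins
dropped (a 1200 × 1200 frame yields nine 400 × 400 tiles).  The leaf
mask subtracts the band with the smallest global mean reflectance from
the band with the largest and thresholds the difference at 0.3
(fraction scale).  Arg-max/arg-min ties resolve to the smallest band
index, deterministically.  The leaf-ratio filter *retains* tiles whose
leaf fraction is ≥ 0.60 — the retention cutoff is inclusive.  The mask
threshold is applied per tile (a per-full-image option would change
which bands are differenced; per-tile is the default because tiles are
the unit every later stage consumes).  No morphological cleanup is
applied; the raw thresholded mask is the contract.

The train/test split is stratified per class — `round(f · n)` tiles to
train, the rest to test, membership drawn from a seeded permutation —
because the pipeline's bookkeeping (50 tiles per species, 1200/300
overall at f = 0.8) assumes exact per-class counts.

## Representative spectra

A tile's spectrum is the mean reflectance over leaf pixels only; a
species' curve is the unweighted mean of its tiles' spectra.  The
dispersion band is the population (ddof = 0) standard deviation across
tiles; the denominator convention matters little at n = 50 and the
population form keeps the single-image case well-defined (sd = 0).
Colour-subgroup contrasts (e.g. red leaf tissue vs the whole leaf) use
a per-pixel predicate; the default calls a pixel "red" when its
reflectance at the band nearest 660 nm exceeds the band nearest
550 nm.  The predicate is user-replaceable; no botanical claim is
attached to the default.

## Band selection

UBS depends only on (B, M): band `k` is `floor(1 + k·(B−1)/(M−1))`,
1-based, so the first and last band are always included for M ≥ 2.
M = 1 is defined as the middle band.

FNGBS semantics, frozen by this package (and by a brute-force loop
reference in the test suite):

1. *coarse* — uniform contiguous partition of the band indices into M
   groups (group g spans `[gB/M, (g+1)B/M)`);
2. *fine* — boundary bands move to the adjacent group whose members
   are closer on average (band distance = squared Euclidean over the
   pixel sample, divided by the pixel count), iterated to a fixed
   point or 50 sweeps; only boundary bands move, so groups stay
   contiguous, and a group's last member never moves, so groups stay
   non-empty;
3. *score* — local density ρ = exp(−mean distance to the band's 3
   nearest other bands) and Shannon entropy H over 256 equal-width
   bins spanning the band's observed range (a constant band has
   H = 0);
4. *select* — per group, the band maximizing ρ·H; ties go to the
   smaller index.

The neighbour count, bin count and iteration cap are conventions, not
tuned values; the data-driven sample is a seeded pool of at most
50,000 leaf pixels drawn from training tiles only.  Entropy is
invariant to affine rescaling of reflectance because the bins span the
observed range.  PCA (scikit-learn, full SVD) is likewise fit on
training pixels only and reports the cumulative explained-variance
fraction; projected component stacks are labelled per component and
exempted from reflectance range checks.

## The classifier

Input `200 × 200 × L`, channels last.  Stem: 5×5/2 conv (64) → 3×3/2
max-pool → 3×3/1 conv (96) → 3×3/2 max-pool.  Three inception modules
with output depths 288/296/480: modules 1–2 have three paths (1×1;
1×1→3×3; 1×1→3×3→3×3 — the stacked pair replaces a 5×5 at equal
receptive field), module 3 has two.  Modules 2–3 downsample by stride
2 **on the final convolution of every path** (a 1×1 path strides its
only convolution); there is no pooling path.  This is the mechanism
that keeps all path outputs concatenable and produces the 25 → 13 → 7
progression under same padding (output size = ceil(input/stride)).
Head: global average pooling → FC-196 → ReLU → 40% dropout → FC-C →
softmax.  ReLU follows every convolution; all conv/FC layers carry
biases; there is no batch normalization.  Model construction computes
the stage trace analytically and from the built layers and fails loud
on any mismatch.

Parameter budget: with L = 6 the stem and head contribute 9,664 +
55,392 + 94,276 + 5,910 parameters; the inception bottleneck (1×1
reduce) widths do not affect the module output depths, so they are
free variables.  `resolve_inception_widths` solves the resulting
five-term linear Diophantine equation by bounded enumeration, ordered
nearest-to-conventional proportions, for a total of exactly 1,388,950;
the solved widths are frozen as the package defaults.  If a different
target has no exact solution the nearest one is returned together with
its discrepancy — never silently absorbed.

The loss is cross-entropy with a base-2 logarithm, summed over the
batch and reported in bits.  Gradients use the natural-log convention
rescaled by 1/ln 2, which is exact; Adam is invariant to that constant
up to its epsilon.  Predicted probabilities are clamped at 10⁻¹² in
the loss.  Training: Adam (β₁ = 0.9, β₂ = 0.999), learning rate
`10⁻³ · 0.9^floor(epoch/5)`, batch 12, random crop to the input size
plus independent 0.5-probability horizontal and vertical flips;
evaluation center-crops without flips.  Inputs are reflectance in
[0, 1] already, so no further standardization is applied.  All
randomness (init, shuffling, crops, dropout) flows from one seeded
generator.  The engine (`hsileaf.nn`) is float32 numpy: window-view
im2col convolutions, argmax-scatter pooling backward, and is verified
against direct-loop convolution and central finite differences.

## Evaluation

All four metrics derive from the confusion matrix (rows = truth).
OA = trace/total.  Precision is macro-averaged over classes
(consistent with macro F1; micro = OA is available), with an empty
prediction column contributing 0.  Macro F1 averages per-class
harmonic means, with 0 for a class whose precision + recall is 0.
Kappa uses expected agreement from the row × column marginals; the
degenerate p_e = 1 case is defined as 0.  Row- and column-normalized
matrices are exported for omission/commission inspection since both
conventions are in circulation.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the target study conditions: 30 classes ×
50 tiles of 400 × 400 × 147 fraction reflectance, background ≤ 0.05,
every tile's leaf fraction at 0.7 (above the 0.6 retention cutoff).
Class spectra are drawn from a parametric vegetation family — blue
floor 0.03–0.07, green peak near 550 nm, red valley down to 0.02–0.05,
sigmoid red edge at 700–725 nm, NIR plateau 0.45–0.60 — and redrawn
until every pair is at least 0.2 apart in L2 over 147 bands (the floor
scales with √(bands/147) on coarser grids so the criterion is
grid-independent).  Leaf coverage is a thresholded smooth random field
(exact fraction, blobby shapes).  Texture motifs (plain / midrib /
edge stripes / spots) modulate mainly the visible bands: colour
patterns in leaves are pigment-driven, while the NIR plateau is
structural and comparatively homogeneous within a species — which also
keeps the two-band difference mask reliable.  Noise is per-pixel
multiplicative log-normal (σ = 0.05) plus additive Gaussian
(σ = 0.005).  Tiles render lazily and deterministically from
(dataset seed, class, tile index), so the default dataset's ~100 GB of
pixels never needs to exist at once.

Deliberately not emulated: shadows, specularities, leaf venation
geometry, radiative-transfer leaf optics, inter-leaf occlusion
statistics, and sensor artifacts.  Passing tests on synthetic data
therefore demonstrate that the pipeline's mechanics are correct and
that the classifier can exploit joint spectral–textural structure;
they do not demonstrate field robustness on real crowns.

## Problem sizes used in the verification suite

The test suite verifies the full-size architecture analytically
(shape trace, parameter count) but trains only a reduced variant: all
channel widths halved, 64 × 64 input, on 5 synthetic classes × 50
tiles of 96 × 96 × 147 with the 3-band uniform selection, 30 epochs at
seed 0.  Fifty tiles per class is the per-class size of the target
study; the spatial and width reductions are chosen so the run
completes in about a minute on one CPU while leaving the learning
problem non-trivial — at these settings two of the five classes
overlap spectrally at the three selected bands and are separated only
by texture, and the reduced network reaches 98% test accuracy
(kappa 0.975).  FNGBS oracle-equivalence fixtures stay at ≤ 12 bands ×
≤ 100 pixels where the quadratic brute-force reference is exact and
fast.

## Known limitations

* The numpy engine is single-threaded-ish (BLAS aside) and meant for
  reduced-scale verification and small real experiments, not for
  training the full 200 × 200 network on thousands of tiles.
* The FNGBS variant here is the package's own freezing of a loosely
  specified family; selected indices on real data will differ between
  variants and samples, and no particular published index set is
  asserted.
* Baseline architectures (reduced AlexNet/VGG variants, GoogLeNet) are
  not implemented; their printed parameter counts (10,865,310 /
  10,404,938 / 15,901,982) are recorded for context only.
* The manual removal of shadowed tiles that a human operator would
  perform is not automated; an optional mean-brightness floor exists
  in the filtering CLI path but defaults off because no defensible
  criterion is available.
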