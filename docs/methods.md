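# Methods

## Problem and model

A candled egg is photographed in transmitted light: the shell and albumen
glow, the yolk(s) absorb and appear as dark shadows. Classification of
single-yolked (SY) vs double-yolked (DY) eggs rests on yolk-shadow *shape*,
not size or color: one roughly circular shadow vs an 8-shaped union of two
overlapping discs. Two classifiers are implemented over one preprocessing
chain; both are deliberately small, since the end use is on-line grading
hardware.

## Preprocessing chain

Channel roles are physical: the warm light source makes the egg body
brightest, and best separated from the dark background, in the red channel,
while the yolk shadow is deepest relative to the albumen in the blue
channel. The chain is: 3×3 median filter (edge replication at borders) on
the red and blue channels; Otsu threshold on the red channel (256 integer
bins, foreground = `pixel > t`, ties to the smallest maximizing t); largest
8-connected component taken as the egg (noise specks can survive
thresholding); its bounding rectangle expanded symmetrically along the
shorter side to a square, padded by 30 px on each side; the blue channel
and the binary mask cropped with that square; background zeroed by mask
multiplication; both resized to 32×32 with bicubic interpolation (the mask
re-binarized at 0.5, and the resized ROI re-masked so the co-registration
invariant `roi = 0` wherever `mask = 0` holds exactly).

Numerical/degenerate choices: a constant grid has no Otsu split — the
constant is returned so binarization yields all-background, with a logged
warning; an image whose largest bright component is below `MIN_EGG_AREA`
(256 px) raises "no egg found"; if the padded square overruns the frame it
is shrunk to the frame and shifted inward, keeping it square and fully
inside (equivalent to clamping and re-squaring from the opposite side).
Coordinates are row-major, 0-based, top-left origin, half-open rectangles.

## Yolk segmentation and Fourier descriptors

Inside the ROI, Otsu splits albumen (bright) from yolk+background (dark);
subtracting the albumen foreground from the egg mask leaves the yolk shadow
plus the thin shell rim, which a 3×3 median filter removes. The Otsu
threshold here is estimated from egg pixels only (the mask): the zeroed
background otherwise dominates the histogram, and for large yolk shadows
the global split collapses to background-vs-egg, leaving no yolk at all.
The binarization is still applied to the whole ROI and the background
always lands in the dark class, so the result is unchanged whenever the
global split would have worked.

The boundary of the largest 8-connected yolk component is traced with
Moore-neighborhood tracing, starting from the topmost-then-leftmost pixel,
orientation normalized to positive shoelace area. Contours are used at
their native traced length N — normalized descriptors are ratios and do
not require resampling to fixed N (a configurable choice).

Fourier descriptors are the DFT of s(k) = x_k + i·y_k. Normalization takes
magnitudes (removing rotation and start point), divides by |a(1)|
(removing scale) and zeroes the DC term (removing translation), giving
d(0) = 0 and d(1) = 1 identically; the feature vector keeps
[d(2) … d(15)], 14 values. A contour whose fundamental vanishes
(|a(1)| ≤ 1e−9 of the largest coefficient — e.g. a doubly-traversed curve)
is rejected as degenerate.

Truncated reconstruction keeps the n lowest-|frequency| coefficients in
the interleaved order u = 0, +1, −1, +2, −2, … (negative frequency
u ≡ N−u); raw indices 0…n−1 alone cannot recover closed shapes. The
reconstruction error ε_n is the mean, over original boundary points, of
the distance to the *nearest* reconstructed point — nearest-point matching
is used because index-wise pairing would make the inner minimum vacuous.

## Fisher discriminant

Class means and the pooled within-class covariance
S_p = Σ_g (n_g−1)S_g/(n−2) define per-class classification functions
f_g(x) = μ_gᵀS_p⁻¹x − ½μ_gᵀS_p⁻¹μ_g + ln p_g. Priors default to equal
(the intended sampling design is balanced) and are configurable. A
near-singular S_p (condition number > 1e12 — NFDs of near-circular yolks
are nearly collinear) is ridge-regularized by λ·trace(S_p)/p with
λ = 1e−6, with a logged warning; this also lets leave-one-out run down to
n = 4, where a held-out fold leaves one class with a single sample. Exact
score ties break toward SY (arbitrary but fixed and logged). Evaluation is
leave-one-out: each sample classified by functions fitted on all others.

Separated-yolk DY images produce two yolk components; only the largest is
traced, so they present a circular contour and are classified SY. This
known limitation is reproduced, not fixed.

## Convolutional network

32×32 ROI scaled to [0, 1] → conv 5×5, 4 maps, sigmoid → 2×2 average pool
→ conv 5×5, 6 maps each connected to all 4 input maps, sigmoid → 2×2
average pool → flatten (150) → fully connected (2) → softmax; 1,012
parameters in total. Training: plain minibatch SGD, fixed learning rate
0.2, batch 50, 100 epochs, per-epoch shuffling (a trailing partial batch
is dropped; when n < 50 the whole set is one batch); no momentum, weight
decay or schedule. The loss is softmax cross-entropy — the canonical
pairing for a softmax output; a mean-squared-error variant (the default of
older toolboxes) sits behind the `loss="mse"` flag. Pooling layers carry
no activation by default; `pool_activation=True` inserts a sigmoid after
each pool for comparison. Weights initialize uniform in
±√(6/(fan_in+fan_out)), biases at zero, seeded. A non-finite loss aborts
with a diagnostic. Evaluation draws repeated stratified 95:5
train/validation splits with a freshly initialized network per repeat and
averages per-class accuracies.

## Synthetic data generator

The generator renders what the algorithms consume, not photorealism: an
axis-aligned bright ellipse on a near-black background, per-channel mean
intensity levels (background/albumen/yolk), a quadratic radial brightness
falloff inside the egg (strength 0.15) standing in for shell-thickness
vignetting, one or two dark yolk discs, and additive Gaussian noise
(σ drawn from 3–7 DN), clipped to [0, 255]. Rendering is a pure function
of the scene, so images are bit-reproducible from their seed. DY disc
centers sit 2r(1−f) apart: f ∈ (0, 1] gives the 8-shaped overlap, f < 0
the separated failure mode (default 5 % of DY scenes, drawn along a
near-horizontal axis so both discs stay inside the ellipse).

Frozen defaults (in `yolkvision.config`): 400×300 frames (preprocessing is
scale-covariant and ends at 32×32 anyway; the egg is sized so the padded
crop square fits inside the frame, which keeps the pipeline
translation-robust), egg semi-axes 95–110 × 70–80 px, yolk radius
34–40 px, intensity levels background (12, 10, 8), albumen (178, 132, 186),
yolk (150, 100, 70). These levels enforce the channel-contrast contracts
(red egg-vs-background ≥ 80 DN, blue albumen-vs-yolk ≥ 40 DN) and were
calibrated once so the ROI-level Otsu split lands between yolk and albumen,
then frozen.

What the generator does *not* emulate: shell texture and speckling, the
candler aperture glow, spectral structure of the light source, off-axis
egg orientation, motion blur. Passing tests therefore demonstrate
correctness of the algorithms on images with the stated contrast
structure, not performance on real candling photographs.

The analytic `figure_eight` contour is the simple closed two-lobed polar
curve r(t) = a(1 + w·cos 2t)/(1+w): a true lemniscate self-intersects and
its lobes cancel in signed area, whereas a traced yolk boundary is always
a simple closed curve.

## Problem sizes and tolerances

The built-in benchmark freezes 200 SY + 200 DY scenes (seed 7, 5 %
separated DY) — large enough for stable leave-one-out rates while keeping
a full run on one CPU in minutes; the CNN benchmark uses 3 repeated splits.
Oracle comparisons use 1e−9 (DFT), exact equality (Otsu, median), 1e−4
relative (gradients vs central differences, float64, h = 1e−5), 1e−6
(descriptor invariance). Timing is reported in logs only; wall-clock
figures are hardware-dependent and never asserted.

## Known limitations

- Single egg per frame; no illumination correction beyond the chain above.
- The separated-yolk DY subgroup is systematically misclassified by the
  discriminant path by construction.
- Boundary tracing assumes blob-like components; 1-px-wide filaments can
  yield degenerate contours, which are rejected rather than repaired.
- Accuracies measured on synthetic scenes do not transfer to real eggs
  without recalibrating the generator against real candling images.
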