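# Methods

This note documents the models, numerical choices and open design decisions
behind `thermarm`, in the spirit of a statistical-software methods appendix.

## Session timing model

A session is `n_sets` sets of `reps_per_set` repetitions at a cadence of
`rep_rate` repetitions per minute (15 in the study protocols), optionally
followed by a passive hold of `passive_s` seconds per set, with `recovery_s`
seconds between sets. Set duration is `reps / rep_rate × 60 + passive_s`.
Timestamps are seconds from the first frame (t = 0 at the start of set 1);
the pre-session acclimation period is outside the recorded timeline. The
frames used for heat maps are those at the beginning (S) and end (E) of
each set; since no frame rate or selection rule is fixed by the protocol,
the package selects the first frame at or after the S time and the last
frame at or before the E time. Multi-set protocols require a strictly
positive recovery so that E_i and S_{i+1} never coincide.

## Skin-temperature dynamics (simulator)

The cumulative temperature offset of the target muscle is piecewise linear
in time: slope `exercise_rate` (default 0.13 °C/min) during each active set,
slope `recovery_rate` (default 0.47 °C/min) during recovery until
`plateau_after_min` (default 3 min) have elapsed within that recovery, then
`post_plateau_rate` (default −0.05 °C/min, a mild decay). The defaults are
the average elevation rates measured for a 10-kg biceps session; an
exponential-saturation model would be more physiological but the measured
quantities are phase-averaged rates, which a piecewise-linear model
reproduces exactly. A zero-weight (passive/control) protocol forces all
rates to zero.

Spatially, a frame is: ambient background (default 25 °C), an elliptical
arm at baseline skin temperature (default 33 °C — plausible values for an
exposed arm indoors; neither is fixed by measurement), plus

* a diffuse arm-wide warming of `nontarget_fraction` (default 0.3) times
  the cumulative offset — this emulates the nonzero warming observed in
  nontarget regions (perfusion, synergist activity);
* a Gaussian hotspot centered in the target muscle's region, with spatial
  sd `hotspot_sigma` (default ≈ 0.09 × frame height). Muscle centers sit at
  0.45 of the ellipse semi-axes — inside the muscle's grid region but clear
  of the silhouette edge, where a hotspot would be unphysical;
* i.i.d. Gaussian sensor noise with sd `noise_sd` (default 0.05 °C, the
  camera's thermal sensitivity).

**Hotspot normalization.** The hotspot amplitude is calibrated so that the
*mean* warming over the target muscle's region (upper half / lower-left /
lower-right of the arm bounding box, the same regions the heat-map analysis
uses) equals `(1 − nontarget_fraction) × offset`; together with the diffuse
share the target-region mean increment equals the modeled offset exactly at
pixel level. This is what makes elevation rates estimated from pipeline
region-mean trajectories recover the configured rates — the property the
simulator exists to provide.

A "vague" scene (classifier class 4) renders the diffuse warming at the
full offset with no localized hotspot.

Right-arm sessions are rendered mirrored, so that the alignment step of the
pipeline (mirror right-arm frames so the biceps side faces left) is
exercised end to end.

### What the simulator does not emulate

Real arm silhouettes (an ellipse stands in), motion between frames,
perspiration and evaporative cooling, vasodilation delays, camera optics
and vignetting, and drift in ambient temperature. Passing tests therefore
show that the *analysis* is correct and well calibrated under the stated
model of the data, not that the model captures every property of real
recordings; in particular the study's real-data numbers (mean S1–E3
difference, real-data classification accuracy) are not reproduced here.

## Preprocessing

Order of operations: align → smooth → segment → crop. Smoothing is a
moving-average filter (default 3×3 — minimal denoising before global
thresholding; kernel dimensions must be odd) with edge replication at the
borders. Segmentation applies Otsu's method on a 256-bin histogram spanning
the frame's min–max range; the returned threshold is the bin center of the
argmax split (the convention of `skimage.filters.threshold_otsu`, which
implements the classical formulation). Foreground is *above* threshold
because skin is warmer than the background. The mask is the largest
8-connected foreground component with holes filled; a user-supplied mask
override replaces the automatic result (stand-in for manual touch-up, no
interactive editing). Frames and masks are cropped to the mask's tight
bounding box. Pixel coordinates are 0-based, row-major, origin top-left.

Empty histogram bins make Otsu's objective exactly flat over a range of
splits; any threshold on such a plateau is a valid maximizer, so tests
compare attained objective values rather than threshold floats.

## Heat maps and regions

The ROI bounding box is partitioned into a 60-row × 20-column grid
("20 divisions along the width, 60 along the height") with near-equal cell
extents: boundary k sits at `floor(k × size / n)`, so cell sizes differ by
at most one pixel. (Dumping all remainder pixels into the last cell was
rejected: with ROIs only slightly larger than the grid it produces one
giant cell and badly distorts region geometry.) Each cell is the mean of
its foreground pixels; a cell with less than half its pixels on the arm is
missing (NaN) and excluded from all region statistics. A region whose cells
are all missing is an error, and such maps are excluded from the classifier
dataset — this quality flag is the package's mechanism for "maps excluded
from the study dataset".

Difference maps are later − earlier (heating positive); the pair notation
"(S1-E3)" names the pair, not a subtraction order. Pair ranking scores each
admissible pair — (S1,E1), (S1,S2), (S1,E2), (S1,S3), (S1,E3) — by the
*target-region* mean of its difference map (the per-session target is
known; whole-map scoring would mix muscles), counts the per-session argmax
with ties broken toward the later pair, and reports floor-rounded
percentages. The floor rule makes the first-and-third-set share of the
study's printed counts come out at 85 % (60/70 = 85.71 → 85); the printed
per-pair percentages themselves mix rounding conventions and cannot all be
reproduced by any single rule.

## Statistics

Elevation rates are `(T_end − T_start) / duration_min`, reported half-even
at 2 decimals (the print precision of the study); raw values are retained.
Trajectories emit target-minus-nontarget region means at each of S1…E3,
aggregated across sessions as mean ± sd per time point. The order-effect
test is Kruskal–Wallis with tie correction, p from the chi-squared
approximation with k − 1 degrees of freedom (group sizes ≈ 10–15 make this
adequate — the null calibration test confirms a 5 % type-I error within
±1 %); a Monte-Carlo permutation p is available via `permutation_reps` for
tiny groups. The per-session quantity fed to the order test is the (S1,E3)
target-region difference, since no other choice is fixed by the protocol;
this is documented rather than configurable.

## Classification

Each session contributes one labeled image per difference pair (default
(S1,E3) and (S1,S3)): missing cells imputed to 0 Δ°C, then min-max
normalized to [0, 1] per image (the class signal is the warming *pattern*,
not the absolute magnitude). The split holds out `floor(0.1 × N)` items
(134 → 121/13). Augmentation is the full factorial of rotations
{−1°, 0°, 1°} × scales {0.9, 1.0, 1.1} × noise {off, on}, 18 variants per
image including the identity combination (the identity scale is included so
that 121 × 18 = 2178); noise is additive Gaussian with mean 0.07 and sd
0.07 on normalized intensities (the sd is a configurable choice; only the
mean is fixed by the recipe), and every variant is resized to
`out_size` × `out_size` (default 244, following the printed recipe —
possibly a typo for 224; configurable either way).

The default model is a compact four-block convolutional network —
(conv 3×3 → ReLU → max-pool 2×2) with 8/16/32/32 channels, a 64-unit hidden
dense layer and a 4-way linear head — implemented in numpy (im2col
convolutions, Adam, softmax cross-entropy), trainable on one CPU in about a
minute at the 64×64 input resolution used throughout. Training inputs are
standardized with the training set's mean/sd, stored on the model. The
recipe is Adam, cross-entropy, learning rate 1e-4, batch 16, 50 epochs.
Training is deterministic under the config seed (single-threaded numpy).

An 18-layer residual network with pretrained initialization is what the
original recipe fine-tuned; with no pretrained weights or real data
available, the package's benchmark uses the small CNN, which reaches 100 %
training accuracy and ≥ 90 % test accuracy on the synthetic benchmark
(chance 25 %). That benchmark — 50 randomized sessions per class including
vague, with per-session baseline/rate/hotspot-position jitter and sensor
noise 0.05 °C — is a scaled-down analog of the study's classification
experiment, not a reproduction of its real-data accuracy.

## Problem sizes and determinism

Simulated studies default to 128 × 96-pixel frames (the spatial layout and
dynamics are resolution-independent; the full 512 × 640 sensor size is the
simulator default for single frames). Parameter-recovery checks use
256 × 192 frames, where single-pixel bounding-box discretization of the
segmented mask — the dominant error source in region-mean trajectories —
is comfortably below the ±0.02 °C/min tolerance. All randomness flows
through `numpy.random.default_rng` seeds; per-module sub-seeds are split
from a root seed so stages are independently reproducible.

## Known limitations

* The ellipse-plus-Gaussian scene is a deliberate idealization; see "What
  the simulator does not emulate".
* Otsu segmentation assumes a single warm object on a cooler background;
  multi-arm scenes and motion are out of scope.
* The region-to-muscle assignment (upper half / quadrants) is fixed
  geometry, valid only for the aligned brachium framing.
* The classifier benchmark's difficulty depends on the simulator's
  between-class geometry; it demonstrates pipeline correctness and
  learnability, not clinical performance.
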