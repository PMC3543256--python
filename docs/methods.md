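# Methods

This note documents the models, defaults and numerical choices behind
`neurogaze`, and what the synthetic benchmarks do and do not show.

## Coordinate conventions

Image coordinates: origin at the top-left pixel centre, x rightward,
y downward; `(x, y)` addresses `pixels[y, x]`. Screen coordinates:
integer pixels `[0, W-1] × [0, H-1]`. All angles in degrees. A pixel
error `e` converts to visual angle as `θ = atan(e · pitch / D)` with
`pitch = diagonal / hypot(W, H)` (a 4:3 screen at 4:3 resolution has
square pixels); at the default geometry (17″, 1024×768, 70 cm) the
small-angle regime holds to well below print precision for all errors
of interest, so whether `atan` or the linear approximation is used is
immaterial — `atan` is used.

## Feature extraction

**Pupil.** Dark-polarity threshold (strict `<`), boundary of the
resulting mask, circle Hough accumulator over radii `[r_min, r_max]`
(unit steps; scikit-image's `hough_circle` provides the vote), global
maximum refined by the centroid of the accumulator values above half
the peak in a 5×5 neighbourhood. Only the centre is wanted, not the
pupil contour, which is why a coarse circle model over the thresholded
mask suffices. A detection with normalized accumulator support below
`hough_min_score` (default 0.25) is treated as not-found; the frame is
skipped, not fatal. With a previous detection, processing is restricted
to a rectangle of half-width `roi_scale × previous radius` (default 4 —
the source protocol names no value) and falls back to the full frame on
a miss.

**Glints.** Bright-polarity threshold, 8-connected labeling
(`scipy.ndimage`), components of area ≥ `min_blob_area`. Centroids are
centres of mass with background-subtracted weights `w = I − threshold`.
The subtraction matters: with raw intensities the uniform pedestal
inside the thresholded support quantizes with the support itself and
biases the centroid by 0.17–0.24 px in our renders, while the
background-subtracted weights vanish smoothly at the component edge and
keep the error below 0.05 px. With threshold 0 the formula reduces to
plain intensity weighting.

**Triangle validation.** Glint pairs define *lines*, not vectors, so
pair directions are folded to [0°, 180°). For every 3-subset of
candidates, the three directions are assigned to the targets
{0°, 60°, 120°} by the minimum-total-deviation permutation (distances
on the 180°-periodic circle, so 179° is 1° from 0°); a subset passes if
every deviation is within `angle_tol_deg` (default 10°) and every side
length lies in `side_range` (default 8–60 px, scaled to the expected
pattern). Among passing subsets the minimal total deviation wins.
Canonical output order: the two endpoints of the near-horizontal side
left to right, then the apex. Tolerances are configuration, set once
per session like the thresholds.

## Gaze mapping

Two independent networks, one per screen coordinate, each 8→10→1 with
tanh hidden units and a linear output; inputs are the raw 8 coordinates
(pupil + three glints), not pupil–glint differences — the centres feed
the networks directly. Inputs are normalized per feature to [−1, 1]
from the calibration min/max; outputs are trained in [−1, 1] units
mapped from the screen ranges and quantized to integer pixels at
prediction (round to nearest, clamp to the screen). The X net is
seeded with `seed`, the Y net with `seed + 1`.

**Training.** Full-batch backpropagation on the MSE for exactly 1000
epochs, momentum 0.95, initial learning rate 0.05, uniform
[−0.5, 0.5] weight initialization, zero biases. The learning rate
adapts with the classic schedule (×1.05 after an improving epoch;
an epoch raising the loss by more than 4% is rejected, the rate ×0.7,
momentum reset). The adaptation is not cosmetic: the 8 inputs are
strongly collinear (four x-like and four y-like channels), which makes
the loss landscape badly conditioned — a fixed rate either crawls
(never reaching even the least-squares level within the epoch budget)
or diverges. The epoch count is part of the protocol and is never cut
short; there is no regularization, early stopping or architecture
search, and a fixed-rate mode remains available
(`TrainConfig(adaptive=False)`).

**Linear baseline.** Ordinary least squares per coordinate on the same
normalized features plus intercept, sharing the normalizers and the
prediction path. It requires ≥ 9 samples and a full-rank design;
noise-free simulated features lie exactly on a 2-D manifold (rank 3
design), so the baseline is deliberately undefined there and the
fitting raises.

## Protocol

Calibration grid: `cols × rows` (default 5×4) positions uniformly
spaced over `[margin·W, (1−margin)·W]` per axis (default margin 5% —
the physical grid offsets of the original setup are not recoverable),
rounded to pixels. Test grid: midpoints of the 2×2 calibration cells
(4×3 by default), disjoint from the calibration points by
construction. All pixel rounding (grid positions, midpoints, POG
quantization) uses round-half-to-even; half-up rounding would break the
grids' mirror symmetry by 2 px.

Schedule: 25 fps; 1200 ms per calibration point (30 frames), 600 ms per
test show (15 frames), 5 shows per test point. The pseudo-random test
order is a seeded permutation of the 60 (point, repetition) shows,
re-drawn until no point repeats back to back (the plausible reading of
a pseudo-random presentation; immediate repeats would be
indistinguishable from a single long fixation).

The three geometric settings (0°/30°/60° between the IR lights and the
camera) are represented as simulator presets and session metadata only;
nothing in the estimator may consume them — that is the free-geometry
principle under test.

## Synthetic data

**Renderer.** Uniform background, iris disk (2.4× pupil radius) and
darker pupil disk with area-coverage anti-aliasing (4×4 supersampling
of boundary pixels; subpixel centres must be recoverable), three
Gaussian spots blended toward the glint level, optional additive
Gaussian noise, quantized to 8-bit. Default levels
(background 110, iris 150, pupil 20, glint 255, σ_glint 2.5 px) are
fixtures chosen for a well-contrasted dark-pupil appearance, not claims
about any physical apparatus.

**Feature-level simulator.** For gaze offset `u = POG − screen centre`,

    s(u) = (1−α)·u + α·S·tanh(u/S)          (per axis, S = 350 px)
    pupil  = rest + g_p ⊙ s(u)
    glints = triangle + g_g ⊙ s(u)
    features += N(0, σ_f²)                   (all 8 coordinates)

with pupil gain `g_p = 0.065 px/px` (an eyeball of ~12 mm radius imaged
at ~11 px/mm rotating ±14° over the screen), glint drift gain
`g_g = 0.012 px/px`, and saturation strength `α = 0.35`. At `α = 0` the
mapping is exactly affine; it is strictly monotone per axis, hence
injective, for any `α ≤ 1`. The saturation models the compressive
response of corneal geometry at large eccentricities — the reason gaze
mapping functions are genuinely nonlinear and a learned mapping is
worth its cost. At the default `α` the best linear fit from features to
POG leaves ≈13 screen px (≈0.36°) RMS of residual; a weaker setting
(α ≈ 0.12, ≈4 px residual) was measured to make ordinary least squares
statistically *superior* to any unregularized 10-unit network under the
default noise (the network's extra estimation variance outweighs its
bias advantage), which would invert the central neural-vs-linear
comparison; the default therefore follows the strongly nonlinear
regime the method was designed for.

**Noise level.** Default feature noise σ_f = 0.5 px, the value whose
pupil-channel POG floor is 0.3° radial
(`σ_f / g_p · √2` per the two axes); `noise_sigma_for_angle` computes
the equivalence, `noise_floor_deg` the induced floor. This floor is
conservative — glint channels add a little information — and matches
realistic centroid jitter for a low-cost camera.

**What passing synthetic tests show.** That the chain detects planted
features to its stated precision, that the learned mapping inverts a
smooth saturating forward model it has never seen, beats the linear
baseline on average, and keeps test-grid accuracy within ~6% of
calibration-grid accuracy under i.i.d. feature noise. Real eyes add
fixational drift (correlated noise), blinks, eyelid occlusion, glasses
reflections and head motion, none of which the simulator emulates;
synthetic accuracy numbers are not predictions of hardware accuracy.

## Known limitations

* **Noise-free mapping recovery is not quantization-limited.** With
  σ_f = 0 the 600 calibration frames collapse onto 20 distinct points,
  and a 10-unit network that interpolates them exactly still has a
  seed-dependent 0.03–0.35° error at the halfway test points —
  measured across fixed-rate GD, adaptive-rate GD, Rprop, Adam,
  Levenberg–Marquardt and L-BFGS — because 20 samples do not pin down
  the nonlinear map between them and nothing (by design: no
  regularization, no early stopping) selects the smooth interpolant.
  The corresponding acceptance test asserts the quantization-floor
  bound (< 0.05°) and fails honestly at ≈0.2–0.3°.
* The per-seed neural-vs-linear comparison is a near coin flip (the
  attainable margin is of the order of the training variability); the
  comparison holds on the mean over seeds, which is how the published
  comparison is framed.
* The Hough accumulator uses unit centre/radius steps regardless of
  `hough_accumulator_step`; the field is validated but coarser voting
  is not implemented.
* Aggregate degree-valued radial RMSE is computed as
  `hypot(RMSE_x°, RMSE_y°)` after converting each component — the
  convention the published tables follow; in pixels the exact identity
  `MSE_ρ = MSE_x + MSE_y` is preserved. The pixel→degree conversion is
  applied to aggregated RMSE values, not per frame (a per-frame variant
  would differ only beyond print precision at these magnitudes).
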