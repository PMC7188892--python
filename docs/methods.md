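# Methods

This note documents the models, parameter choices, numerical details and
known limitations of somatrack, in the order of the processing pipeline.
All distances are micrometres, all times seconds, all intensities camera
units (a.u.); point coordinates are (z, y, x) physical positions obtained
as voxel index times the sampling step, so the ~10x axial:lateral sampling
anisotropy lives in the units rather than in the indices.

## Acquisition model and input handling

The reference acquisition is a two-channel (nuclei + calcium) sequence of
3D stacks: 45 planes of 256x512 px, 0.16125 µm pixels, 1.5 µm z-step, one
stack per 0.9 s, stored as a 5D 16-bit TIFF with a YAML sidecar for the
geometry and the stimulus windows.  Axis order is declared as a
five-letter string (default `XYZTC`) listing axes from fastest- to
slowest-varying; voxel values round-trip bit-exactly.

**Corrupted frames.**  A sporadic acquisition artifact can wipe out whole
stacks.  No published criterion exists for flagging them, so the detector
is ours: a frame is corrupted when the robust z-score of its
nuclei-channel median (against the median/MAD over frames, MAD scaled by
0.6745) exceeds 5.  At most 20% of frames are ever flagged, worst first —
a guard against a drifting baseline being misread as mass corruption.
Flagged frames are replaced by per-voxel linear interpolation in time
between the nearest good frames (copied at the ends); linear is the
cheapest scheme consistent with replacing a frame by "interpolated data",
and the repair is idempotent.

## Anisotropy correction

`interpolate_axial` inserts `ceil(z_step / pixel_size) - 1` planes (9 for
the reference geometry) between consecutive planes using natural cubic
splines fitted independently per (y, x) column.  Original planes are
written back verbatim at their knot indices, so they are preserved
bit-exactly; spline undershoot is clamped at zero.  This equalises the
sampling but cannot sharpen the axially elongated PSF — the gain is that
the isotropic 3D convolutions of the detection step become meaningful.
The ceiling (rather than rounding) makes the interpolated axial step the
largest step not exceeding the lateral pixel, i.e. voxels are never left
coarser axially than laterally.

## Spot detection

The sole tuning parameter is the average nucleus diameter (default 3.0 µm
for Kenyon-cell nuclei), measurable from data as the mean FWHM of 1D
intensity profiles (x and y, background-subtracted, sub-pixel half-max
crossing) through isolated nuclei.  Diameter and Gaussian scale convert
via FWHM = 2.3548 σ.

The filter bank holds 10 sigmas log-spaced over [0.5, 1.5] x the nominal
sigma — the published description fixes only "around the average nucleus
diameter", so the range and spacing are our choice; log-spacing gives
constant relative scale steps.  Per scale: 26-neighbourhood local maxima
(borders excluded by one voxel; an equal-valued plateau that strictly
dominates its surround yields one maximum at its centroid, so ties never
multiply detections), then a two-component Gaussian mixture fit (EM,
k-means++ init, 3 restarts, tol 1e-6 on the log-likelihood, ≤200
iterations, seedable) on the maxima intensities.  The split threshold is
where the posterior responsibility flips between the components.

**Degeneracy.**  A scale is skipped when the fit is degenerate: component
means within one pooled standard deviation, or separated by less than 50%
of the dim (background) mean.  The second condition is needed because EM
will happily halve the narrow unimodal intensity distribution of a
signal-free stack into two components that are "well separated" on the
noise scale yet nearly identical on the scale a nucleus would reach;
requiring the bright mode to sit substantially above the background mode
rejects such stacks while leaving genuine nuclei/background splits (an
order of magnitude apart) untouched.

Foreground maxima from all scales are painted with the original stack
intensity into an empty grid, merged by a Gaussian convolution at the
nominal sigma, and the final detections are the local maxima of the
merged grid, in physical coordinates.

## Registration

**Rigid chain.**  For each consecutive frame pair, one random subset of
100 points is drawn from each cloud and optimally coupled by the
Hungarian algorithm (squared-Euclidean cost).  Because partially
overlapping subsets couple many non-corresponding points, a plain
least-squares similarity fit on the coupled pairs suffers severe
regression dilution (isotropic scale biased to ~0.85 even on clean data).
The fit is therefore trimmed: pairs are pre-aligned by a translation
(zero, or the component-wise median displacement, which is robust to the
mismatch majority), pairs with residual above 3 µm are dropped, and the
closed-form absolute-orientation (Umeyama) solution is re-fitted while
the trim radius shrinks (3 → 1.5 → 1 µm).  Both trimmed fits, the pure
median translation, and the identity are scored by the mean
nearest-neighbour distance of the fully transformed cloud to the target
cloud — the very objective the registration serves — and the best
candidate becomes A*_t.  This keeps the published contract (one subset
draw, Hungarian coupling, least-squares similarity) while making the
estimate robust; the candidate scoring adds one KDTree query per frame
pair.  Transforms compose onto the mid-sequence reference (floor(T/2);
frames after the reference chain backwards).  Frames without detections
are bridged by element-wise interpolation of neighbouring composed
matrices (adequate for the small inter-frame motions involved).

**Non-rigid refinement.**  Each rigidly aligned frame is registered
directly to the reference cloud with non-rigid Coherent Point Drift
(implemented in-package): the moving points are Gaussian-mixture
centroids drifting toward the reference, with displacements expanded on a
Gaussian kernel G_ij = exp(−‖y_i − y_j‖²/2β²) so that nearby somata move
together.  Defaults: β = 2 nucleus diameters (6 µm) — the coherence
scale of tissue deformation; λ = 3 (fit/smoothness trade-off); tol 1e-5
on the relative objective change; ≤150 iterations.  The outlier weight w
defaults to 0: with the standard uniform-component formulation, any
appreciable w puts most posterior mass on the outlier term at moderate
variance and stalls the drift (a pure 1.5 µm translation was only
partially recovered at w = 0.1, and exactly recovered at w = 0); the
responsibility softmax itself already down-weights far points, and 5%
spurious detections do not disturb the w = 0 fit in our benchmarks.
CPD does not guarantee improvement on every input, so `register_sequence`
keeps the rigid positions for any frame whose mean nearest-neighbour
distance to the reference CPD would worsen — this enforces the documented
invariant (non-rigid never increases the mean NN distance) as a
safeguard rather than assuming it.

## Tracking

DBSCAN runs on the registered (z, y, x) coordinates of all frames pooled,
ignoring time.  Parameters are estimated from the data: min_pts =
max(2, round(0.5 T)) — a soma must be detected in at least half the
frames to seed a cluster — and eps at the knee (maximum deviation from
the chord) of the sorted min_pts-NN distance curve, capped at the nucleus
radius so adjacent somata are never bridged.  Both are overridable.

A cluster whose median detections-per-frame rounds (banker's rounding) to
n > 1 merged n somata and is split by k-means (k = n, k-means++, 10
restarts, seedable).  Per frame, duplicate detections resolve to the one
nearest the cluster centroid (position flagged `deduplicated`); missing
frames are linearly interpolated in registered space between the nearest
detected frames, with nearest-available copies at the ends, and mapped
back to original coordinates by removing the frame's CPD displacement
(nearest-detection lookup) and inverting the frame's composed similarity
transform.  Detected positions keep their stored original coordinates
exactly.  Clusters supported by fewer than 3 distinct frames are
discarded — interpolating a one-detection "trajectory" over a whole
sequence is meaningless.  Every surviving trajectory covers every frame,
and no detection contributes to more than one trajectory.

## Signal

Per frame, a discrete 3D Voronoi partition seeded by that frame's soma
positions assigns every voxel within 1.5x the nucleus radius of its
nearest seed (ties to the lowest soma id); regions are disjoint by
construction and deliberately local.  The raw trace F[i, t] is the mean
calcium-channel intensity over soma i's region; an empty region (all
voxels captured by neighbours) falls back to the seed voxel with a
warning.

Normalization: order-2 Butterworth low-pass at 20% of Nyquist, applied
forward-backward (zero phase; the order is our choice, the mildest
standard roll-off), then ΔF/F = (F_s − F0)/F0 with F0 the moving average
of the smoothed trace over [t−10, t+10], truncated (not padded) at the
sequence ends and floored at 1e-6 x the global median of F to avoid
division blow-up.  ΔF/F is scale-invariant: normalize(cF) = normalize(F)
for any c > 0.  A soma is responsive in a window when its ΔF/F strictly
exceeds 0.1 at some frame of the window.  Stimulus windows follow the
protocol timing at 0.9 s per frame (air pulse 45–50 s → frames 50–55,
octanol 85–90 s → frames 94–99) extended by 5 frames past offset to
capture the slow indicator decay, whose extent the protocol itself does
not define.

The glow-control filter iteratively removes, among all pairs closer than
twice the soma size, the globally dimmest member (ties to the lower id),
until all pairwise separations comply; the global dimmest-first order
makes the retained set independent of input ordering.  Batch alignment
multiplies all traces of a batch by P99(reference)/P99(batch) of the
shared reference condition's peak distribution (the 99th percentile, not
the max, to resist outliers).  The per-fly quality control is our
substitute for an unpublished procedure: a fly fails when fewer than 5
somata respond in the first odor window, or when the fraction of somata
"responding" during pre-stimulus baseline frames exceeds half the
odor-window fraction (non-specific activity).

## Synthetic data

The simulator is the validation instrument, so its defaults are the study
conditions: 2,000 nuclei of 3 µm diameter packed into an ellipsoid
occupying 40% of the 45 x 256 x 512 volume (evenly spaced by k-means on
uniformly sampled foreground voxels, in physical coordinates), 120 frames
at 0.9 s.  Rendering draws solid spheres on a fine isotropic grid,
convolves with an anisotropic Gaussian PSF (σ_lateral 0.2 µm, σ_axial 3x
that — plausible for spinning-disk confocal; the true PSF would be
measured from isolated spots), subsamples axially to the acquisition
anisotropy and adds clamped Gaussian noise (σ = 30 on a log-normal
per-nucleus brightness around 1,000, spread 0.3) — center detectability
of ≥3 noise sigmas above background is asserted in the tests.  With a
template stack, the foreground comes from Otsu's threshold (largest
connected component) instead of the parametric ellipsoid.

Motion applies to all centres jointly: a random-walk drift (0.08
µm/frame/axis), a random-walk rotation (0.002 rad/frame), Poisson(2 per
sequence) erratic whole-volume shifts of ~2 µm per axis (the pulsatile
organ), and ≤3 sinusoidal deformation modes (amplitude 0.3 µm,
wavelength of the order of the volume, slow phase drift) evaluated on
the initial positions so the displacement field is spatially smooth and
temporally coherent.  Under these defaults the distance between
neighbouring nuclei varies by <10% over the sequence — the tissue
hypothesis the tracker relies on, asserted in the tests.  Calcium
transients on a responsive subset (default 20%) rise instantaneously at
a stimulus-window onset (0–2 frame jitter) and decay exponentially with
τ = 2 s; peak ΔF/F is log-normal around 0.5.  These transient parameters
are plumbing for the signal-module tests, not measured values.

What the simulator does *not* emulate: photon-shot statistics (noise is
additive Gaussian), a vectorial/measured PSF, autofluorescent background
structure, bleaching, and z-dependent aberrations.  Passing tests
therefore demonstrate the algorithmic pipeline under realistic geometry,
density, motion and SNR — not robustness to every optical artifact of
real acquisitions.

`inject_detection_noise` bypasses the image stages for fast tracking
benchmarks: per frame it drops true points with a miss probability,
jitters survivors, and adds uniform spurious points — the degradation
profile of the real detector.

## Evaluation

Detection: a detection within 1.5x the nucleus radius of a ground-truth
centre is a TP; each sphere yields at most one TP (extras are FP);
out-of-sphere detections FP; empty spheres FN; no TN exists.  Score =
Jaccard = TP/(TP+FP+FN).  Matching is one-to-one, nearest pair first
(an assignment-optimal variant is available behind `method="optimal"`);
greedy is the default because contention is rare at the acceptance
radius and the greedy result is ordering-invariant.

Tracking: only complete trajectories are scored; each is assigned
one-to-one to ground-truth tracks by ascending mean-over-time distance,
TP within 3x the nucleus size (generous mostly for axial imprecision),
otherwise FP; unmatched truth tracks are FN.

Annotations import from ImageJ Cell-Counter XML (marker x/y as pixel
indices, z as 1-based slice: z_um = (slice−1) · z_step) or a CSV dialect
(`type, z_um, y_um, x_um`).

## Problem sizes

The bundled checks run at desk-check sizes chosen to preserve the
full-scale conditions rather than the raw counts: the static detection
benchmark keeps the 500-nuclei-per-full-volume packing density in a
reduced field of view; the dynamic tracking benchmark uses 200 nuclei
over 40 frames with 10% missed / 5% spurious detections and full-strength
motion; the end-to-end image run uses 20 nuclei at ~100 µm³ of tissue per
nucleus with motion scaled to its reduced field of view.  The full-scale
run (2,000 nuclei, 120 frames, whole images) is the same code at
`SimulationConfig()` defaults and takes hours rather than minutes.

## Known limitations

- The rigid chain accumulates error linearly in T between the reference
  and the sequence ends; CPD absorbs what remains, but very long
  sequences would benefit from a multi-reference scheme.
- CPD is O(n²) per frame in memory and time; at 2,000 points per frame it
  is the pipeline's second cost after image convolution.
- The DBSCAN parameter estimation assumes a soma is detected in at least
  half the frames; sequences with worse detection rates need a lower
  `tracking.support_fraction`.
- Back-mapping of interpolated positions inverts the similarity transform
  exactly but approximates the CPD displacement by nearest-detection
  lookup; the error is bounded by the field's smoothness scale β.
- The fly-level quality control and the corrupted-frame criterion are
  reconstructions of procedures whose published descriptions are not
  specific enough to reimplement verbatim.
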