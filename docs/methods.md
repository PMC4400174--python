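# Methods

This note records the signal model, the segmentation procedures, the
synthetic data the package is validated on, and the numerical choices made
where the design was genuinely open. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Acquisition model

A swept-source intravascular OCT system digitizes one spectral interference
fringe per A-line: 1600 samples at 14 bits on two orthogonal polarization
channels, 1024 A-lines per catheter rotation, one frame per 200 µm of
pullback (260 frames ≙ 5.2 cm), 6.5 µm per reconstructed depth pixel. A
frequency shifter in the reference arm moves zero optical delay to a carrier
frequency, so positive and negative delays occupy distinct fringe
frequencies and both sides of the zero-delay line are usable ("full-range"
imaging). `AcquisitionConfig` carries this geometry; all of it is
overridable, and the test suite mostly runs scaled-down geometries
(e.g. 200–400 samples, 128–256 A-lines, 12–20 frames) so the whole suite and
the acceptance script finish in well under a minute on one CPU.

## Reconstruction

Per A-line, with padded length `L` (next power of two ≥ `n_samples`,
1600 → 2048):

1. subtract the per-channel background fringe (recorded with the sample arm
   blocked), multiply by the spectral window (Hanning by default), zero-pad
   to `L`;
2. FFT; assemble a `2L` spectrum `[X[L/4:L/2] | zeros | X[0:L/4]]` — the
   second quarter (carrier band and above) to baseband, the first quarter
   wrapped to the negative frequencies at the top; inverse FFT gives the
   demodulated complex fringe. The placement convention is pinned by a test:
   a pure-carrier cosine must demodulate to DC. A fringe sampled at
   quarter-rate carrier supports signed depths `|d| < L/4`; this bound is
   enforced by the simulator (a depth at ±L/4 would fold at DC or Nyquist);
3. linear-spline resampling at the calibrated k-map positions (uniform
   wavenumber), then multiplication by `exp(-i·dispersion_phase)`;
4. FFT, `10·log₁₀(|·|² + ε)` with `ε = 1e-12` (so an all-zero fringe maps to
   the display floor deterministically), fftshift so depth 0 is centered,
   crop to the configured image height (default 1024 rows, centered; the
   side kept is configurable), linear map from a configurable dB window
   (defaults 45–115 dB, chosen so the simulator's default amplitude scale
   fills the upper half of 8 bits) to [0, 255].

The two polarization channels are reconstructed independently and their
linear-scale depth powers summed before the log map (polarization-diverse
detection); identical channels therefore raise levels by 3 dB without
changing structure. All stages are A-line independent and verified against a
hand-coded O(n²) DFT oracle on small vectors (1e-9 tolerance).

Window-before-pad ordering: background subtraction → window → zero-pad →
FFT. The window has `n_samples` support; padding after windowing keeps the
padded tail exactly zero.

## Synthetic fringes

No public raw pullbacks exist, so the inverse model generates them. Per
scatterer at signed depth `d` and amplitude `a` (digitizer counts):

```
fringe[n] = background[n] + Σ a·cos(2π·(L/4)·n/L + 2π·d·u(n)/L + φ(n)) + noise
```

`u(n) = n + k·(L/2π)·sin(2πn/L)` is the nonlinear wavenumber sampling map
(strictly monotone for |k| < 1; monotonicity is validated), and `φ` a
polynomial dispersion phase in the centered, normalized sample coordinate.
The carrier rides the uniform digitizer clock — it is an electro-optic
frequency shift — while the depth-encoding term follows the laser sweep, so
k-linearization straightens depth chirp without touching the carrier. The
calibration generator stores the k-map as resampling positions
`k_map[m] = 2·u⁻¹(m/2)` on the demodulated grid and the dispersion phase
evaluated at those positions; the simulator derives `u` and `φ` back from
the stored arrays by interpolating the inverse relation, so simulator and
reconstruction are consistent by construction rather than by shared code.
Samples are quantized to integer counts and clipped to the digitizer range;
the background is integer-valued so that a scatterer-free, noise-free
simulation reproduces it exactly. Everything is deterministic per seed, and
at zero noise the seed has no effect.

The simulator is calibrated in grid units (pixels, cycles per record), not
physical wavelengths: every downstream computation is grid-based, and the
hardware's optical parameters enter only through the pixel pitches.

## Phantom pullbacks

The phantom generator renders 8-bit polar frames directly (an additive
fringe model cannot produce shadows, which segmentation depends on):

* eccentric circular lumen: the catheter sits at a configurable offset
  inside a circle of radius 160 px; the surface depth per A-line follows the
  ray-circle intersection, and the wall is a 110 px band decaying from 185;
* catheter sheath: a 3-row line of 230 at depth 30;
* guide-wire: a 36-A-line, 12-row blob of 255 near the catheter with a
  full-depth shadow (×0.04) beneath — the shadow, not the blob, is what the
  en face detection keys on;
* struts: Gaussian spots (σ = 2 px, amplitude 255) at `lumen − distance`
  casting rectangular shadows (±2 A-lines, ×0.05), ~6 per frame, at least
  18 A-lines apart and clear of the guide-wire; apposed distances are drawn
  from [0, 8] px and malapposed from [19, 28] px around the 15 px threshold
  (a constructor error if a "malapposed" distance does not exceed the
  threshold);
* additive Gaussian noise, default σ = 6 counts, then clipping to [0, 255].

The ground-truth table (lumen contour, strut positions/distances/labels,
guide-wire intervals, sheath depth, stent frame range) is exact by
construction and re-measurable on the zero-noise rendering. What the phantom
does **not** emulate: speckle statistics, birefringence contrast between the
polarization channels, blood artifacts, side branches, multi-stent
pullbacks, and struts with very weak reflections — passing tests therefore
demonstrate the correctness of the chain's logic and its noise robustness at
the stated level, not clinical-grade performance on patient data.

## Stent region selection

The en face image averages each A-line over depth (A-lines × frames). It is
contrast-stretched so the brightest pixel maps to 255, filtered with the
8-neighbor Laplacian `[[1,1,1],[1,−8,1],[1,1,1]]` (absolute response,
clipped to [0, 255]), and thresholded at 240. Strut spots and shadows
perturb the depth average sharply, so the response concentrates around them.
A window of `⌈stent_length/pitch⌉ + margin` frames (150 by default) slides
over the columns; the window with the largest mask count wins, ties going to
the smallest first frame, and the reported range is trimmed to the first and
last frame in the window containing any evidence (which is why reported
ranges can be narrower than the window). Contrast stretching rather than
rank equalization makes the fixed 240 threshold meaningful: rank
equalization of a nearly flat region spreads pure noise over the full range
and the Laplacian then fires everywhere. An optional small-component removal
exists for noisy data and is off by default.

## Segmentation

Order per frame: sheath → guide-wire → lumen → struts → malapposition.
Constants live in `SegmentationParams`; pixel units throughout.

* **Sheath**: row with the highest mean intensity within the top 20% of
  rows, ties to the smallest row; the sheath row ±2 (and everything above)
  is masked out of later steps.
* **Guide-wire, step 1** (per pullback): Otsu-binarize the en face, dark
  class = shadow; 3×3 morphological closing then opening (edge-padded so
  shadows touching the first/last frame survive); per frame the largest dark
  run of A-lines is the candidate interval.
* **Guide-wire, step 2** (per frame): ROI = candidate ± 40 A-lines with zero
  rows prepended (so erosion cannot clip the top); Otsu; 3×3 erosion; 5×5
  top-hat of the erosion subtracted from it — for binary images this equals
  the 5×5 opening and severs bridges narrower than the element, separating
  the wire from touching noise; connected-component labelling keeps the
  largest component overlapping the candidate columns. An empty result falls
  back to the step-1 interval.
* **Lumen**: per A-line, the first row below the sheath where the
  depth-median-smoothed intensity exceeds an Otsu-derived tissue threshold
  *and* stays bright over a persistence window (≥ 70% of the next 25 rows).
  The persistence requirement is what distinguishes wall from strut: a strut
  blob is bright for ~10 rows and then shadowed, the wall for 100+. A-lines
  without a persistent surface (guide-wire and strut shadows) are filled by
  circular linear interpolation and flagged. Crossings deviating more than
  3 px from a local median baseline (computed over the 9 nearest *valid*
  samples, so interpolated gaps cannot drag it) are rejected as
  strut-blob-tail artifacts and re-interpolated. Fewer than 50% valid
  A-lines marks the frame unsegmentable.
* **Struts**: per A-line outside the guide-wire, a candidate needs a peak
  ≥ 220 (tested on the raw frame — smoothing erodes the narrow spot; noise
  singletons die in clustering) within [lumen − 30, lumen + 5] rows and a
  distal shadow (mean < 40 over rows peak+6 … peak+46). Candidates are
  clustered by union-find over pairs with A-line gap ≤ 1 and depth
  difference ≤ 5 px; groups of < 2 A-lines are discarded; strut position is
  the member median. The contour across each strut ± 4 A-lines is then
  re-interpolated from flanking wall (the first bright crossing there
  follows the strut body, not the wall) before distances are measured.
* **Malapposition**: `distance = max(0, lumen − strut depth)` along the
  A-line (radial, not Euclidean); malapposed iff strictly greater than
  15 px = ⌊100 µm / 6.5 µm⌋. Monotone in the threshold by construction.

Scoring against ground truth uses greedy nearest-first one-to-one matching
within 5 A-lines and 5 px (both exposed as parameters);
sensitivity = 100·TP/(TP+FN), specificity = 100·TN/(TN+FP), reported to one
decimal. Strut detection reports no specificity — strut absence has no
well-defined true-negative population.

## Visualization

Bilateral filter (σ_spatial = 3 px, σ_range = 25 levels), histogram
equalization to [0, 255], then the piecewise remap `v < 128 → 0`,
`v ≥ 128 → round((v−128)·200/127)`, compressing tissue into the wall band
[0, 200] and zeroing residual noise. Features overwrite: lumen interior 0,
guide-wire 210, apposed struts 230, malapposed struts 255 — distinct values
inside the reserved 201–255 band so colorization is a pure lookup. The
polar→Cartesian warp (A-line 0 along +x, counter-clockwise) samples wall
values bilinearly from a label-free copy and labels nearest-neighbour, so no
blended pseudo-labels can appear; the same split applies to the 512×512
resize. The lumen center is the shoelace (area) centroid of the contour
polygon — the vertex mean is biased toward the near wall because A-lines
sample the contour uniformly in angle as seen from the off-center catheter,
and recovers only half the eccentricity. Renders are orthographic
maximum-value projections with an optional half-volume cutaway; because the
encoding is ordered by clinical priority, a plain max is also a priority
projection. The physical aspect ratio (frame pitch vs in-plane pitch) is
recorded in the volume metadata rather than resampled into the voxel grid.

## Pipeline and backend rule

`run_push_of_button` chains reconstruct → select-region → segment → render,
always writing stage artifacts (every stage is independently inspectable)
and a sorted-key summary JSON, byte-identical across reruns of the same
inputs. An empty strut-evidence mask records a "no stent detected" outcome
and skips segmentation; any stage failure aborts with a stage-named error.
`select_backend` implements the placement rule for heterogeneous execution —
host iff `T_d + T_d' > T_d2h + T_h + T_h2d + T_h'`, ties to the accelerator —
as a pure function; this reference implementation itself is host-only, since
the CPU/GPU split is performance engineering, not semantics.

## Known limitations

* The lumen and strut detectors are functional re-designs matched to the
  phantom's qualitative appearance (first persistent crossing; peak plus
  shadow), with all constants exposed; they are not tuned against clinical
  images.
* The fringe simulator and the phantom are disjoint: fringes exercise
  reconstruction, the phantom exercises segmentation and visualization. An
  additive scatterer model cannot cast shadows, so a fringe-level pullback
  cannot currently carry detectable stents end to end; the full-pipeline
  path is validated on fringes for the no-stent outcome and on phantom
  stacks for segmentation onwards.
* Offset-binary vs sign-extended storage of 14-bit samples is not modelled;
  any constant offset is absorbed by background subtraction.
* Single stent region per pullback; no neointimal coverage or bifurcation
  analysis.
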