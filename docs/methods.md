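# Methods

`shwfs` simulates a Shack–Hartmann wavefront sensor (SHWFS) and compares
two reconstruction pipelines on it: the classical per-sub-aperture
pipeline, and a whole-frame pipeline that extracts every spot from the
full detector image with a matched filter and matches spots to lenslets
with a permutation-invariant point-set network. This note records the
model, the conventions, the numerical choices, and what the synthetic
benchmark does and does not show.

## Wavefront model and conventions

A wavefront over the circular pupil is a modal sum
φ(x, y) = Σₖ aₖ Zₖ(x, y) of Zernike polynomials.

* **Ordering** — OSA/ANSI single index `j`, with double-index labels
  Zₙ^m; `j = (n(n+2)+m)/2`, negative `m` = sine harmonic. The
  reconstructed set is the first 15 modes minus piston (j=0) and the two
  tilts (j=1,2): 12 modes, Z₂^−2 … Z₄^4. Excluded modes keep their `j`
  slots (as zeros) in every coefficient vector.
* **Normalization** — unit RMS over the unit disk (Noll-style), so a
  coefficient is that mode's RMS contribution in waves and, for
  piston-free vectors, wavefront RMS = ‖a‖₂. The dynamic-range metric is
  an RMS in waves, so this convention makes per-mode ranges directly
  comparable. Both conventions are explicit in serialized output because
  per-mode results are meaningless without them.
* **Evaluation** — every mode is expanded once into an exact Cartesian
  monomial table; values and gradients are evaluated termwise. Gradients
  are therefore analytic (no recurrences, no quadrature), which the test
  suite checks against central finite differences at 10⁻⁶.
* **Random wavefronts** — coefficients are independent zero-mean
  Gaussians with standard deviation ∝ (n+1)^(−11/6) (a Kolmogorov-like
  spectrum standing in for a Karhunen–Loève turbulence weighting: low
  orders dominate, as in ocular aberration statistics), piston/tilt
  zeroed, then rescaled to a target RMS drawn uniformly from a
  configurable interval (module default 0.1–2.0 waves). True KL
  eigenfunctions of a phase covariance are out of scope; any alternative
  spectrum can be injected through the sampler config.

## Sensor forward model

Reference configuration: 16×16 lenslets, lenslet size 500 µm, focal
length 6.5 mm, 20×20 detector pixels of 10 µm per sub-aperture window
(320×320 px frame), λ = 500 nm.

Two scales coexist on this sensor card: the lenslet pitch (500 µm) fixes
the pupil's physical radius, R = N·pitch/2 = 4 mm, while each lenslet's
detector window is 20 px × 10 µm = 200 µm. We read this as an effective
relay magnification between the lenslet plane and the CCD and keep both
numbers: pupil-plane slopes use R, detector displacements use the pixel
size directly, Δx[px] = f·g / pixel. A slope of 1.5385·10⁻³ rad under
f = 6.5 mm then displaces a spot by exactly one 10-µm pixel.

* **Effective sub-apertures** — a circular pupil inscribed in the lenslet
  grid. Default rule (`mask_rule="cell"`): a lenslet is effective iff its
  whole square cell lies inside the unit disk (164 of 256 lenslets at
  16×16; 32 of 64 at 8×8). This leaves at least one lenslet of detector
  margin beyond every effective window, which is what makes the
  beyond-sub-aperture regime physically observable: spots can leave their
  window and still land on the CCD. Under the alternative `"center"` rule
  the outermost effective windows touch the detector edge, so expanding
  modes (defocus of one sign, one axis of astigmatism) push their spots
  off-chip at exactly the classical failure point and no algorithm could
  do better than the classical one there. `"full"` disables masking.
* **Slopes** — per sub-aperture, the mean of the analytic wavefront
  gradient over the lenslet cell by midpoint quadrature on a 41×41 grid
  (41 rather than a coarser rule so that the matrix entries stay within
  10⁻⁴ of a dense quadrature even for the coarse cells of scaled-down
  sensors). The same quadrature builds the reconstruction matrix, so the
  forward model and the reconstructor are consistent by construction.
* **Spots** — geometric (slope-based) propagation: true spot center =
  reference center + f·(mean slope), rendered as a circular Gaussian of
  σ = 1.0 px (≈ the diffraction scale λf/pitch for the reference sensor;
  the profile width is config). Intensities are pixel-integrated (erf
  differences), unit flux per spot, clipped at the detector edge,
  noiseless. Photon/read noise, pixel crosstalk, lenslet aberrations,
  extended (retinal) source structure and Fraunhofer diffraction are
  deliberately out of scope.
* **Coordinates** — 0-based pixels, pixel centers at integers,
  x = column, y = row (downward). All centroids are global-frame pixels.

## Centroid extraction

**Classical window CoG.** Intensity-weighted mean position over the
lenslet's own M×N window. If the window's total intensity falls below
10⁻⁶ of the frame maximum the spot has left the window and the window
center is returned — i.e. the measured displacement is zero, which is
precisely how the classical algorithm mistakes a large local distortion
for a flat patch. When a neighboring spot intrudes, the window CoG
reports the common centroid of both spots. Both failure modes are
reproduced in tests.

**Whole-frame matched filter.** The frame is correlated with a Gaussian
template (width matched to the rendered spot by default; configurable to
study template mismatch) as a frequency-domain product, zero-padded to a
linear correlation; for a symmetric template, correlation and convolution
coincide. The k strongest response peaks are taken iteratively: global
argmax (row-major first-maximum on exact ties), sub-pixel refinement on
the *unsuppressed* response, then a disk of ⌈3σ⌉ px around the integer
peak is zeroed before the next search. Exactly k centroids are returned,
anywhere on the frame; exhausting the response earlier raises with the
count found.

**Sub-pixel refinement.** Gaussian-weighted centroid of the bilinearly
subsampled response (half-width 3 px, 10 sub-pixels per pixel, weight
σ = template σ), run as a fixed-point iteration in which both the window
and the weight are re-centered on the running estimate. A single pass
with the weight centered on the integer peak is biased toward that pixel
by the factor σ_r²/(σ_r²+σ_w²) (σ_r = response width); the iteration's
fixed point removes this bias exactly for an untruncated Gaussian
response. Measured accuracy on rendered frames: ≲3·10⁻⁴ px (half-width 2
truncates the window and is an order of magnitude worse, which is why the
default is 3). Stopping tolerance 5·10⁻⁵ px, ≤60 iterations; a flat or
non-positive window returns the integer peak.

## Spot-to-lenslet matching

Matching is a per-point classification over an unordered set of k
centroids (k = effective lenslets). The network is a symmetric-function
point-set classifier:

* shared pointwise encoder 2 → 64 → 512 (the first stage consumes the
  (x, y) pair, later stages are 1×1), ReLU + batch norm;
* elementwise max pooling over the k points → one 1×512 global feature,
  invariant to point order;
* pointwise head on [per-point 512 ‖ global 512] → 256 → k scores, ReLU +
  batch norm except the last stage; softmax per point.

A single global classifier cannot label every spot, so the head is
segmentation-style: each point's feature is concatenated with the global
feature before the final pointwise stages. Since all per-point operations
share weights and max is symmetric, {point → score vector} is invariant
to input order by construction (the suite asserts this to 10⁻⁶, and
bit-identity of the global feature).

Input coordinates are normalized to [−1, 1] per axis by the frame extent.
Labels are one-hot lenslet ids; training data come from the simulator
(render → extract → label each centroid by optimal matching to the true
spot positions; ambiguous samples are dropped with a warning). A fast
`analytic` path uses the true spot positions directly for large runs.
Loss is softmax cross-entropy; the optimizer is Adam (learning rate 10⁻³,
batch 8, 50 epochs in the full protocol; first-moment coefficient 0.9 —
the protocol's "momentum"; the quoted decay-rate range is implemented as
a step learning-rate factor, default 0.7 every 10 epochs). The network
and its training loop are implemented directly on NumPy in float32
(explicit backprop, verified against numerical gradients in the tests);
the model is small enough that a scaled sensor trains in minutes on one
CPU core.

**Training amplitude range.** The matcher is only useful if it has seen
out-of-window configurations, so training wavefronts are drawn with RMS
uniform on an interval that spans the *extended* range: 0.5–55 waves at
16×16, 0.5–35 waves at 8×8 (chosen so peak displacements reach ~1.5
window widths — the on-chip margin of the cell mask rule). With the
module-default 0.1–2.0-wave interval, displacements never exceed ~1 px
and the network would never learn the regime it exists for.

**Assignment.** Per-point argmaxes can collide, so the final mapping is a
bijection: greedy highest-confidence-first with exclusion (default), or
optimal linear assignment on log-probabilities (`method="optimal"`). Two
irreducible degeneracies are detected and flagged with warnings, never
resolved: centroids closer than a minimum separation (merged/overlapping
spots — an extended blob is indistinguishable from two overlapped ones)
and centroid pairs sharing the same top-2 candidate lenslets (the swap
ambiguity: if two spots trade windows, no frame-only algorithm can tell).
The benchmark conditions avoid these regimes by construction; frames
whose spot count differs from k are out of scope.

## Modal reconstruction

Slopes g = (centroid − reference)·pixel/f per lenslet, interleaved
(Gx, Gy) into a 2m-vector G. The reconstruction matrix D (2m×n) holds the
sub-aperture-averaged analytic mode gradients (same quadrature as the
forward model) scaled to slope units; A = D⁺G with the pseudo-inverse by
SVD, discarding singular values below 10⁻⁶ of the largest (rank
deficiency past the cutoff warns with the condition number). The
classical pipeline feeds window-CoG centroids with the identity
assignment; the proposed pipeline feeds whole-frame centroids with the
network assignment. Tilt is not in the solved set; residual global tilt
is reported as the mean residual slope.

Reconstruction error against a reference wavefront is the RMS of the
pointwise difference of the two synthesized maps over the pupil raster
(256² default; with unit-RMS modes this equals the coefficient-difference
norm to the quadrature error, which the tests verify), and the relative
error divides by the reference RMS (undefined and flagged for a zero
reference).

## Dynamic-range benchmark

Per mode: raise the lone coefficient from `step` in increments of `step`,
run the full pipeline at each amplitude, and record the largest
coefficient (= wavefront RMS) whose relative reconstruction error stays
within the threshold (1%). The sweep stops at the first failure
(monotone-stop; re-entries past a failure are not searched). Improvement
per mode: δRMS = (RMS_ours − RMS_classical)/RMS_classical × 100%. One
network, trained once on random wavefronts, serves all modes. Because the
coefficient *is* the wavefront RMS under unit-RMS normalization, sweeping
the coefficient and sweeping the RMS are the same thing here.

**Problem sizes.** The full protocol (16×16, 10,000 wavefronts split
9000/1000, 50 epochs, 0.05-wave steps) is the package default
(`RunConfig()`). The benchmark that the test suite and the acceptance
script actually run is the scaled protocol (`scaled_run_config()`): 8×8
lenslets (all physical parameters unchanged, k = 32), 800 training
wavefronts with RMS 0.5–35 waves rendered and extracted end to end, 30
epochs, 0.25-wave sweep steps — about ten minutes on one CPU core for
training plus all 24 sweeps. On this protocol every one of the 12 modes
gains dynamic range (roughly +50% to +240% depending on seed), with the
low-order modes (defocus, astigmatism) gaining at least as much as the
highest-order mode — the same ordering the full-scale method reports.

## Numerical choices

* Quadrature: midpoint 41×41 per lenslet cell (≤10⁻⁴ of dense quadrature
  at both sensor scales); cached per geometry.
* SVD cutoff 10⁻⁶ (relative); the 12-mode systems here are
  well-conditioned (condition number ~2).
* Ties in peak search: row-major first maximum (documented, tested).
* Degenerate inputs: empty windows → window center; flat refinement
  window → integer peak; exhausted response → error naming the count
  found; zero-reference relative error → flagged None.
* Float32 for the network (speed), float64 everywhere else.
* Determinism: every random path takes a seed (sampler, dataset
  shuffling/splitting, training batches, init); repeated runs with equal
  seeds are bit-identical in-process.

## What the synthetic benchmark shows — and what it does not

The generator emulates the study conditions: noiseless pixel-integrated
Gaussian spots displaced by the geometric slope model, first 15 Zernike
modes, turbulence-weighted random coefficients. Passing tests therefore
demonstrate the *algorithmic* claim — whole-frame extraction plus learned
matching extends the per-mode dynamic range by large factors over window
CoG on the same frames — under ideal detector physics. They do not
demonstrate robustness to photon/read noise, stray light or multi-layer
reflections, non-Gaussian or spatially varying spot profiles (real
retinal spots), diffraction sidelobes, or miscalibration of the reference
centers; all of these degrade both the matched filter and the matcher in
ways this simulator cannot measure.

## Known limitations

* **Classical range vs the geometric bound.** The textbook half-window
  bound for the classical pipeline assumes a zero-width spot. With σ=1 px
  spots, window-truncation bias breaks the 1% criterion while the
  fastest spot's center is still ~1.4 px inside its window edge, so the
  measured classical defocus range (18.8 waves at 16×16) sits ~14% below
  the zero-width bound (21.9 waves); the spot-radius-corrected bound
  (half-window − ~2σ) brackets the measurement. The sweep resolves the
  crossing itself to one step; the discrepancy is a property of the
  bound, not of the sweep.
* **Degeneracies.** Overlapping/merged spots and swapped spot pairs are
  detected and flagged, never resolved — they are information-theoretic
  limits of a single-frame sensor, and they are what ultimately ends the
  proposed pipeline's dynamic range.
* **Fixed k.** The extractor always returns exactly k centroids and the
  matcher assumes exactly k points; frames with missing or extra spots
  are out of scope.
* The matcher must be retrained per sensor geometry (checkpoints carry a
  geometry hash and loading against a different geometry warns).
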