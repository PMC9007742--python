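# Methods

This note documents the models, conventions and numerical choices behind
`opmkit`, and what the synthetic benchmarks do and do not establish about
real microscope data.

## Coordinate conventions and the deskew transform

The world frame is right-handed: **z** is the optical axis (depth, 0 at the
coverslip), **x** the scan axis, **y** the sheet-width axis; all voxel grids
are 0-based with half-open ranges. A raw acquisition is a stack of camera
frames indexed (scan *s*, row *y*, column *x′*), where *x′* is the in-sheet
propagation direction tilted by *θ* from the coverslip. The sample at
(*s*, *y*, *x′*) lies at

    x = x₀ + s·Δs + σ·x′·p·cos θ,   y = y·p,   z = x′·p·sin θ

with scan step Δs, sample-space pixel *p*, scan origin x₀, and σ = +1 for
view 1 (illumination at +θ) and σ = −1 for view 2 (−θ). Deskewing inverts
this map onto an orthogonal grid with default voxel sizes
(vz, vy, vx) = (p·sin θ, p, Δs); any other grid can be requested. Axial
samplings used in practice vary with the resampling choice of the pipeline
that stored the data, which is why the output grid is a parameter rather
than a constant.

Both the deskew and the synthetic forward model evaluate the analytic map
in one `scipy.ndimage.map_coordinates` pass with linear interpolation.
A chained shear-then-scale decomposition would bound memory on very large
stacks, but at the sizes this package targets a single evaluation is
simpler and avoids resampling the data twice; the map itself is identical.

Because the sheet of view 1 leans toward +x with depth, covering voxels
near x = 0 at depth requires scan positions at negative x; the forward
model starts the scan early and records the offset in
`AcquisitionGeometry.scan_origin_um`, which deskew honours.

**View orientation.** In this forward model the σ = −1 mapping alone puts
the deskewed second view into the same world orientation as the first: the
instrument's camera-image mirror and the opposite shear compose into that
single sign change. The residual between the two deskewed views is
therefore a pure origin offset, removed by `overlap_crop` (crop to the
common world support, ≤ 0.5 voxel of rounding); fine registration handles
the rest. `flip_view` — an exact x-mirror and involution — is kept for data
deskewed under the wrong-view convention by other software.

## Synthetic data

The generators are pure functions of (spec, seed) and always return ground
truth with the data.

- **Bead phantoms**: anisotropic Gaussians with exact requested FWHMs,
  principal axis z″ rotated by a configurable tilt in the xz plane,
  positions uniform under a minimum-separation constraint (dart throwing
  with restarts; an infeasible packing raises). Poisson noise is applied to
  expected counts, then optional Gaussian read noise; values are clipped to
  the 16-bit range only at export.
- **Two-view scenes**: per view, the scene is multiplied by a Beer–Lambert
  transmittance exp(−μ·L) along the ±45° illumination path entering at the
  coverslip side. The path integral is discretized along the 45° diagonal
  with a step of one voxel diagonal (this requires vz = vx); occluders are
  fully opaque ellipsoids casting hard shadows, which makes shadow tests
  unambiguous. Optionally a Gaussian light-sheet profile along y weights
  the illumination. Each view is then rendered to oblique frames with the
  forward model.
- **Scene texture**: white noise smoothed at σ = 1.5 voxels, squared, with
  a Tukey border taper. This emulates punctate nuclear labelling on a dark
  background. The taper matters: with a domain-filling texture, any
  correlation-based shift estimator locks onto the static image frame — an
  artifact no real specimen produces.
- **Drift series**: a fixed template shifted per time point by a known
  random-walk or linear trajectory (subvoxel, linear interpolation).
  Outliers are never painted into images; `inject_outliers` corrupts a
  chosen fraction of *measurements* with ±mag offsets, emulating spurious
  correlation peaks.

What the generators do **not** model: diffraction and the instrument PSF
applied to scenes (beads carry the PSF analytically; scenes do not),
refraction, scattering beyond straight-ray Beer–Lambert attenuation,
camera fixed-pattern noise, and stripe artifacts. Passing benchmarks on
these phantoms validates the geometry, the estimators and the solvers, not
photometric realism.

## Phase correlation

The translation between two volumes is the argmax of the inverse transform
of the normalized cross-power spectrum, refined per axis by a parabolic fit
through the peak and its two neighbours (wrap-aware, |δ| ≤ 0.5). Frequencies
whose cross-power magnitude is below 10⁻⁶ of the maximum are excluded: they
sit at the numerical noise floor and carry garbage phase. Confidence is the
correlation peak normalized by its achievable maximum (all retained
frequencies coherent) — a phase-coherence score in [0, 1]; constant inputs
return zero shift with confidence 0.

A Gaussian spectral low-pass weight (`lowpass_sigma`, default 1 voxel,
equivalent to correlating smoothed images) is applied to the whitened
spectrum. Pure translations remain exact because the weight is symmetric,
and the smooth unimodal peak keeps the parabolic refinement well
conditioned. The weight is essential inside warp registration: when the
displacement varies across a chunk, high frequencies decohere, and pure
whitening — which weights them equally — buries the coherent peak. The
registration loop widens the weight in proportion to the chunk size
(chunk/16, minimum 2 voxels), where larger chunks hide more internal
deformation.

## Multi-scale warp registration

Iteration *i* splits both volumes into f_i chunks per axis — dyadic
(2, 4, 8, 16) by default; a 2·i rule and explicit factor lists are
selectable — with 25% overlap per axis to stabilize edge vectors. Each
chunk pair yields one translation and confidence; chunks with variance
below a floor get confidence 0, and vectors below the confidence floor
(default 0.1) are replaced by inverse-distance-squared interpolation from
accepted nodes. The node field is upsampled with a cubic spline (linear
when any axis has < 4 nodes; constant extrapolation beyond the outer
nodes), composed with the accumulated field as
total′(x) = inc(x) + total(x + inc(x)), and the moving volume is re-warped
from the original before the next iteration. Iteration stops at the
maximum count (default 4) or when chunks would fall below the minimum size
(default 32³). The returned `WarpField` holds the composed field sampled at
the finest chunk centres plus per-node confidence. `apply_warp` is a
backward warp with linear interpolation; a zero field is a bit-exact
identity on integer grids. The field is applied backward and the spline is
cubic — choices, documented as such, since the direction and order are not
dictated by the procedure itself.

Dyadic splitting reaches the 32³ floor from ~512³ in exactly four
iterations, which is why it is the default rule.

## Fusion

Per view, quality = Gaussian-smoothed (default 8 voxels) Sobel-gradient
magnitude. The blend map is the argmax selection (exact ties 0.5) feathered
by a Gaussian (default 4 voxels); feathering a binary map and its
complement preserves w₁ + w₂ = 1 exactly. Fusion is the convex combination
w₁·v₁ + w₂·v₂, hence pointwise bounded by the inputs and symmetric under a
view swap. The smoothing and feather scales are declared defaults, not
calibrated values; one practical constraint is that a shadowed region
narrower than the smoothing scale can be overwhelmed by its own shadow-edge
gradient, so the metric scale should sit below the size of the occlusions
of interest. Frequency-domain fusion variants are deliberately out of
scope.

## Dehazing and illumination correction

Dehazing is the white top-hat: data minus its grey-scale morphological
opening at `scale_voxels` (default 40). The opening is anti-extensive, so
the operation is nonnegative, bounded by the input, and *exactly*
idempotent. An optional Gaussian smoothing of the envelope (clamped back
below the data) is available for very noisy frames but trades away exact
idempotence; it is off by default after measurements showed an
envelope-smoothing variant violating idempotence by far more than the
intended tolerance. The scale must sit well above the feature size and
below the background scale.

Illumination correction divides each y-plane by the calibrated Gaussian
sheet profile (peak-normalized); gains are clamped at 1/ε (default ε = 0.05)
and clamped planes are flagged, since planes that received almost no light
cannot be restored, only amplified. The profile is a calibration input, not
estimated from data.

## Temporal stabilization

For each time point, relative shifts to its 2·n nearest temporal
neighbours (n = 7; edge time points clip to what exists) are measured by
phase correlation. With A the per-frame absolute shift and one row
−1…+1 per pair, the system R = M·A is solved per axis (it is separable;
solving axes jointly or independently is identical). The gauge freedom is
fixed by anchoring A₀ = 0 — stabilize to the first frame. The L1 residual
norm is minimized by iteratively reweighted least squares: 50 iterations,
weight 1/√(r² + ε²) with ε = 10⁻⁶, initialized from the weighted
least-squares solution; phase-correlation confidences multiply the rows as
soft prior weights. The "L1" here is data-fidelity robust regression — the
motivation is outlier measurements in R — not a sparsity penalty on A. The
plain least-squares solver is retained (`method="l2"`) as the comparison
baseline. A disconnected pair graph is rejected with the unreachable time
points named.

Breakdown behaviour: with gross ±50-voxel outliers the L1 solution is
essentially exact through ~10% corruption; at 20–30% isolated near-edge
time points can break when, by chance, a majority of their few links are
corrupted with mutually consistent signs, while the bulk of the trajectory
stays accurate. This is a property of the estimator, not of the
implementation.

## LS³ scan-timing model

The galvo ramps linearly at `galvo_rate` during each exposure and returns
with a raised-cosine flyback inside the readout window (the flyback shape
is cosmetic; only its completion before the next exposure matters). The
stage ramps continuously. Residual blur per exposure is
|v_stage − v_galvo|·t_exp — exactly zero at matched rates — and the
uncompensated blur is v_stage·t_exp. Throughput: frames = ⌈range/step⌉ with
step = v_stage·(t_exp + t_read), duty cycle t_exp/(t_exp + t_read). A sweep
exceeding the galvo's optical half-range (±150 μm of a ~300 μm total)
raises a warning. Defaults are illustrative; the model is kinematic and
ignores galvo electromechanics and camera shutter details.

## File formats and pipeline

On disk: multi-page uint16 TIFF (pages = z or scan s, rows = y, cols = x or
x′) with a JSON sidecar carrying the acquisition geometry or voxel
metadata; floating-point data written to TIFF is linearly quantized with
the scale and offset declared in the sidecar (round trip within one count).
Large intermediates go to a chunked zarr directory store, 32-bit for
floats, losslessly compressed. The pipeline stages run in the fixed order
deskew → dehaze → register → fuse → illumination-correct → stabilize; a
config selecting them out of order, or with unknown stages or keys, is
rejected at validation. Every run logs stage parameters and SHA-256
checksums of its outputs; identical configs reproduce identical checksums.
On failure the failing stage is named and a marker file is left beside any
partial outputs.

## Benchmark problem sizes

The shipped tests and the acceptance script use desk-scale fixtures chosen
to exercise every code path at meaningful statistics: bead volumes of
110×220×220 voxels at 100 nm (12 beads, shot-noise SNR ≈ 20), registration
fixtures of 128³ (translation) and 256³ (sinusoidal warp, amplitude 4
voxels, wavelength 128), drift series of 50 time points, and two-view
occlusion scenes of 40×32×96 μm. Full-scale acquisitions (10⁹–10¹⁰ voxels
per time point) run through the same code paths via the chunked store but
are not part of the test suite.

## Known limitations

- The warp model is pure per-chunk translation; rotations or shears inside
  a chunk are only captured piecewise.
- Fusion assumes registered, photometrically comparable views; no
  intensity normalization model is applied.
- The PSF fit is three 1D Gaussians after one in-plane rotation, matching
  the rotate-then-fit calibration procedure; it is not a full 3D PSF model
  and does not decompose aberrations.
- Stabilization is translational only.
- Attenuation is straight-ray; no refraction or multiple scattering.
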