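# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, in the spirit of a methods appendix.

## From coordinates to images

ICCS operates on intensity fluctuations, so localization lists are first
re-imaged. Each event contributes one isotropic 2D Gaussian of standard
deviation `psf_width` (nm). **"Width" always means the Gaussian sigma**,
not FWHM — conventions differ across the field, and the choice
propagates: the e⁻¹ radius of the autocorrelation of sigma-width spots is
w = 2·sigma, so a 50 nm rendering width implies 100 nm fitted auto
widths. Sigma is carried on every `RenderedImage` and echoed in pipeline
reports.

Per-pixel values are exact Gaussian masses integrated over the pixel
extent (separable error-function differences), truncated beyond
5.5 sigma; the discarded mass is < 1e-7 per event, so a localization well
inside the grid contributes 1.0 to the image sum to better than 1e-6.
Each event has unit mass by default — ICCS here measures *positional*
correlation; photon weighting is available behind a flag but couples the
estimate to brightness statistics. Both channels must be rendered on one
grid (same extent, pixel size); the default extent is the padded bounding
box of the *whole* table for exactly this reason.

Defaults: 10 nm/pixel, sigma 50 nm. A 50 nm spot blurs the multiple
emissions of one antibody complex into a single object, which is what
makes the pixel approach robust to event redundancy (see below); 10 nm
rendering is available for display but is not the analysis default.

## Correlation surfaces

For channels a, b and a binary region of interest M:

G_ab(ξ, η) = ⟨δI_a(x, y)·δI_b(x+ξ, y+η)⟩_M / (⟨I_a⟩_M ⟨I_b⟩_M),

with δI = I − ⟨I⟩_M. Implementation: δI is zeroed outside M, the raw lag
products are computed by zero-padded FFT correlation, and each lag is
divided by the number of overlapping ROI pixel pairs, itself the FFT
autocorrelation of M (rounded to integers). This *masked normalization*
handles ROI restriction and image boundaries in one mechanism and avoids
the wrap-around contamination of periodic FFT correlation. `roi=None`
uses an all-ones mask through the identical code path, so a full-frame
mask reproduces the unmasked result bit for bit.

Degenerate inputs: a zero-mean (empty) region raises; a constant nonzero
image yields an all-zero surface (δI ≡ 0), which downstream fitting
reports as zero amplitude. Lags with no overlapping ROI pairs are NaN and
excluded from fits. A brute-force evaluator of the definition
(`correlation_direct`, shift-and-mask per lag) ships with the package as
the independent oracle; FFT and direct agree to ~1e-13 relative on random
images with and without masks.

## Gaussian fits and the ICCS estimators

Each surface is fitted over the full 2D disc of lags (default radius =
`max_lag` = 32 pixels = 320 nm at the default pixel size, ≥ 3× the
largest expected correlation width) with

G(ξ, η) = G₀ · exp(−(ξ² + η²)/w²) + G∞.

Initialization: G∞ = median of the rim lags, G₀ = zero-lag excess,
w = 2 pixels; trust-region least squares with w bounded positive.
Non-convergence never raises — the `converged` flag and residual RMS are
reported. The (0,0) lag is included by default: rendered Gaussian images
have no shot-noise delta peak (a flag excludes it for histogram-style
renderings). Radial averages are computed for plotting only; fits always
use the full 2D data.

Coefficients follow the standard ICCS amplitude convention:
M₁ = G₀_cross/G₀_auto2 (fraction of channel-1 particles with a channel-2
partner), M₂ = G₀_cross/G₀_auto1, f_ICCS = (M₁+M₂)/2. M values are
reported raw — noisy fits can exceed 1 or go negative — with a clamped
convenience value in [0, 1].

The correlation distance uses the broadening quadrature
d = √max(0, w²_cross − (w²_auto1 + w²_auto2)/2), floored at zero (with a
flag) when the cross width does not exceed the pooled auto width:
negative broadening is noise, and the estimator must be total.

**Width cap.** On uncorrelated data the free cross fit can latch onto
long-range density structure with a huge width and a spurious amplitude.
Since colocalization broadening satisfies w²_cross = w²_auto + d² with d
of PSF scale, a cross width beyond 3× the pooled auto width is not a
colocalization signal; the cross surface is then refitted with the width
capped at that bound (flagged). This keeps local-map cells and
negative-control fields well behaved without touching genuine signals
(a planted 120 nm distance at 50 nm rendering fits at ~226 nm width,
well inside the cap).

**Estimator biases** (characterized by the validation suite, inherent to
the amplitude formalism, not corrected):

- *Brightness dispersion.* Amplitudes are brightness-weighted: if emitter
  i produces K_i localizations, E[M] ≈ f_true·⟨K⟩²/⟨K²⟩. Uniform
  duplication (every event k times) cancels exactly — measured shift
  < 1e-11 — which is the pixel method's redundancy robustness. *Dispersed*
  K (e.g. Poisson blinking) biases f downward by ⟨K⟩²/⟨K²⟩.
- *Broadening dilution.* Pair distance and localization noise broaden the
  cross-correlation; at fixed correlated mass the amplitude scales as
  w²_auto/w²_cross, so f is mildly underestimated for separated pairs
  (≈ 4% at 10 nm noise, ≈ 17% at d = 40 nm with 50 nm rendering).
- *Distance floor.* For separations below the rendering width, d returns
  small positive values of order the localization noise scale rather
  than the true separation; for larger separations the Gaussian fit to
  the ring-convolved cross-correlation *over*states d (e.g. ≈ 200 nm
  fitted for 120 nm planted). The package exposes the model expectation
  (`predicted_distance_estimate`: PSF autocorrelation convolved with the
  orientation ring, fitted by the same Gaussian model, pushed through
  the same quadrature) so measured values can be compared with the
  estimator's own expectation; recovery agrees with it to ~1–3 nm.

## Local analysis

`local_iccs` tiles the field with square windows (default 69 pixels,
odd, stride = window/2) and runs the full estimator per tile with a
smaller lag range (default 16 pixels). Cells are invalid — NaN in the
f/d maps — when ROI coverage is below 25%, a fit fails, or the tile is
degenerate (empty). The stride is configurable; overlapping tiles give a
smoother map at the cost of correlated cells.

## Fiducial drift correction

Fiducial nanodiamonds never blink: they produce a localization in
essentially every frame at a fixed position, while single fluorophores
are ON in ≪ 1% of frames. Detection therefore pools all localizations,
hashes them on a grid of cell size `capture_radius` (default 100 nm),
refines cluster centroids, and accepts clusters whose *frame occupancy*
(fraction of reference frames containing a member) reaches
`min_occupancy` (default 0.5 — orders of magnitude above any blinking
duty cycle). Under selective-excitation keyframing the reference frames
are the keyframes (default interval 1000 frames), and trajectories are
linearly interpolated between them. The capture radius must exceed the
expected drift excursion plus noise; for uncorrected random-walk drift
of tens of nm, 300 nm is a safe choice. A cluster that swallows > 20% of
all events with many events per frame triggers a pathological-clustering
warning.

Drift at frame f is the mean over tracks of (position at f − position at
frame 0), interpolated per track, then smoothed by a centered moving
average (pipeline default 101 frames ≈ 2 s) and re-anchored to zero at
frame 0. Two boundary details matter. First, referencing each track to
its noisy frame-0 position injects that noise as a constant offset into
the whole trajectory; because the offset passes through the linear
filter, subtracting the *smoothed* frame-0 value cancels it. Second, the
filter pads ends by mirroring — padding with the frame-0 sample (which
is exactly zero) would leave half the offset in place. The smoothing
window trades localization noise (∝ 1/window) against random-walk
curvature bias (∝ window); for 3 tracks with 10 nm noise and
0.5 nm/frame drift steps the optimum is broad around a few tens of
frames, and the 101-frame default recovers such drift with ≈ 4 nm RMSE
over 15,000 frames. Drift is estimated per channel independently
(fiducials are visible in both channels; independent estimates absorb
chromatic offsets). After correction, all events within
`exclusion_radius` (default 150 nm — the 40 nm fiducial size plus
rendering width) of a track's mean position are removed before
correlation analysis.

## Confocal registration and masks

Matched fiducial landmarks (from drift tracks and a confocal spot list;
`match_landmarks` pairs unordered sets by mutual nearest neighbour after
centroid alignment) feed a least-squares transform in physical nm
coordinates. The default model is *similarity* (translation + rotation +
isotropic scale): confocal and widefield share the objective, so shear
is unexpected; affine and pure translation are available. Collinear or
coincident landmarks raise a conditioning error; the RMS landmark
residual is attached to the transform.

Focus segmentation is deliberately simple and replaceable: global Otsu
threshold (or mean), 8-connected components, minimum area (default 20
confocal pixels at the default 70 nm confocal pixel size), no border
clearing. Masks are resampled onto the rendered grid by pulling each
target pixel center back through the inverse transform with
nearest-neighbour sampling — set-pixel counts survive rotation to within
~2% resampling tolerance. Masked ICCS is the global estimator with the
transferred mask as ROI.

## The simulator

`simulate_dataset` emulates a dual-color acquisition: channel-1
particles uniform in the field; a planted fraction `f_true` receives a
channel-2 partner at exactly `pair_distance` with uniform random
orientation (the localization noise, not the pairing, supplies the
spread — this keeps distance-recovery oracles clean); remaining
channel-2 particles are independent. Each particle emits
K ~ Poisson(mean, minimum 1) localizations in uniformly random frames
(`emission_model="fixed"` plants a deterministic count instead, used by
the recovery benchmarks to isolate the estimator from the ⟨K⟩²/⟨K²⟩
brightness bias documented above), each displaced by isotropic Gaussian
noise. A per-frame drift trajectory (none / linear / random walk) shifts
every event; fiducials are localized in both channels every keyframe
with the same noise and drift. Blinking is modeled as *random-frame*
multiple localizations without ON-dwell structure: the analysis consumes
time-integrated images, so photophysical kinetics are irrelevant here —
which also means the simulator cannot exercise frame-correlated
artifacts. Other real-data features it does not emulate: camera noise
and PSF-fit failures, nonuniform labeling density, chromatic aberration
fields, axial (z) structure, inhomogeneous background. Passing tests
therefore validate the estimators and the pipeline plumbing, not
robustness to every experimental pathology.

Defaults mirror a typical acquisition: 10 × 10 µm field, 2000 particles
per channel, 15,000 frames, ~8 localizations per emitter, 10 nm
precision, 3 fiducials. The positive-control preset pairs every particle
at 15 nm (the secondary-antibody scale of a same-protein double label);
the negative preset uses independent distributions (f_true = 0).
`simulate_two_population` plants different fractions inside and outside
synthetic foci, and `simulate_confocal` renders those foci at
diffraction-limited resolution (70 nm pixels, Poisson noise) for
segmentation and registration fixtures.

## Problem sizes and numerical tolerances

Validation benchmarks run on 1000 × 1000-pixel renderings (10 × 10 µm at
10 nm/pixel) with 2000 particles per channel and 10 seeds per condition;
driftless scenarios use 1000-frame tables since the analysis is
time-integrated. Drift benchmarks use the full 15,000 frames. A global
analysis of a 2000 × 2000-pixel pair (three FFT correlations + fits)
completes in seconds on one CPU; the dominant cost is the padded FFT,
independent of the number of localizations. Oracle equivalence is
asserted at 1e-8 relative (measured ~1e-13); fit self-consistency at
1e-6; fraction recovery within 0.05 absolute; distance recovery within
10 nm of the convolution-model expectation; drift RMSE below 5 nm.

## Known limitations

- f_ICCS is a *relative* amplitude ratio: labeling efficiency, blinking
  dispersion and broadening dilution all scale it below the true bound
  fraction; absolute stoichiometry would require fluorophore-per-antibody
  calibration, which is out of scope.
- d is reliable only between roughly the localization noise scale and
  ~2 rendering widths; outside that range it is a floor or a
  model-dependent overestimate (use `predicted_distance_estimate` to
  interpret it).
- Drift correction assumes ≥ 1 persistent fiducial per channel; there is
  no fiducial-free (redundant cross-correlation) fallback, and no axial
  drift handling.
- Registration supports affine-family transforms only; nonlinear
  chromatic field maps are out of scope.
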