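# smlm-iccs

Nanoscale colocalization analysis for dual-color single-molecule
localization microscopy (SMLM/dSTORM) by **image cross-correlation
spectroscopy (ICCS)**, with fiducial-based drift correction and
correlative confocal masking.

## The problem

dSTORM produces a *list of molecular coordinates* — one localization per
detected blinking event over thousands of frames — rather than an
intensity image. Quantifying whether two labeled species colocalize at
the sub-100 nm scale from such lists is awkward for object-based methods:
the same antibody blinks many times (event redundancy), coordinate
clustering is parameter-hungry, and dense nuclear signals defeat
segmentation. This package takes the pixel-based route instead:

1. **Re-image** each channel's coordinates as a superposition of Gaussian
   spots of fixed width (default sigma = 50 nm, about one
   antibody-complex footprint) on a shared grid (default 10 nm/pixel).
2. **Correlate**: compute the spatial auto-correlation of each channel
   and the cross-correlation of the pair over a region of interest,

   G_ab(ξ, η) = ⟨δI_a(x, y) · δI_b(x+ξ, y+η)⟩ / (⟨I_a⟩⟨I_b⟩),

   by FFT with masked normalization (fluctuations δI = I − ⟨I⟩ taken over
   ROI pixels only, each lag normalized by its ROI-overlap pixel count).
3. **Fit** each surface with G(ξ, η) = G₀·exp(−(ξ²+η²)/w²) + G∞ and form
   the amplitude-ratio coefficients M₁ = G₀ᶜʳᵒˢˢ/G₀ᵃᵘᵗᵒ²,
   M₂ = G₀ᶜʳᵒˢˢ/G₀ᵃᵘᵗᵒ¹. Their arithmetic mean is the **colocalized
   fraction f_ICCS**; the broadening of the cross-correlation gives the
   **correlation distance** d = √max(0, w²ᶜʳᵒˢˢ − (w²ᵃᵘᵗᵒ¹+w²ᵃᵘᵗᵒ²)/2).
4. **Map locally**: the same analysis on sliding 69 × 69-pixel subregions
   yields f and d maps across the cell.

Around this core the package provides the full experimental pipeline:
detection of persistent fiducial markers (fluorescent nanodiamonds, which
never blink) in the localization stream, per-channel drift estimation and
correction, excision of fiducial regions, landmark registration of
diffraction-limited confocal images to the SMLM frame, focus segmentation
(e.g. γH2A.X DNA-damage foci), and ICCS restricted to the registered
mask. A seeded simulator generates dual-color localization streams with
planted ground truth (colocalized fraction, pair distance, blinking
redundancy, localization noise, drift trajectories, fiducials, synthetic
confocal images) so that every stage is testable without external data.

Intended users: microscopists and image analysts working with dual-color
SMLM coordinate tables (any software export; CSV/TSV with a column
mapping) who want quantitative colocalized fractions and distances
instead of visual overlap.

## Worked example

```python
from smlm_iccs import (SimulationConfig, simulate_dataset, render_image,
                       compute_iccs)

cfg = SimulationConfig(
    extent=(10_000.0, 10_000.0),          # 10 x 10 um field, nm units
    n_particles_1=2000, n_particles_2=2000,
    f_true=0.6, pair_distance=15.0,       # 60% paired at antibody scale
    loc_precision=10.0,                   # nm localization noise
    mean_localizations_per_particle=1, emission_model="fixed",
    n_fiducials=0, n_frames=1000, seed=7)
table, truth = simulate_dataset(cfg)

img1 = render_image(table, "ch1", pixel_size=10.0, psf_width=50.0,
                    extent=(0, 0, 10_000, 10_000))
img2 = render_image(table, "ch2", pixel_size=10.0, psf_width=50.0,
                    extent=(0, 0, 10_000, 10_000))
result = compute_iccs(img1, img2)
print(f"M1 = {result.m1:.3f}, M2 = {result.m2:.3f}")
print(f"f_ICCS = {result.f_iccs:.3f}")
print(f"d = {result.distance_nm:.1f} nm")
```

Output:

```
M1 = 0.573, M2 = 0.566
f_ICCS = 0.569
d = 25.2 nm
```

Of the 2000 channel-1 particles, 1200 were planted with a channel-2
partner 15 nm away; the amplitude ratios recover that fraction (0.57 vs
0.60 — the small deficit is the cross-correlation broadening by pair
distance and localization noise, see `docs/methods.md`). The distance
estimate sits at the estimator's floor for separations below the 50 nm
rendering width: at this scale d reports "closer than one PSF", not an
exact separation.

The same analysis runs from the shell:

```bash
smlm-iccs simulate --preset positive --seed 1 -o locs.csv --truth truth.json
smlm-iccs iccs locs.csv -o result.json
smlm-iccs run --preset positive --seed 1 --n-rois 3 --output-dir out/
```

`run` executes the full pipeline (drift correction from fiducials,
fiducial exclusion, rendering, global ICCS, local maps, optional masked
analysis) and writes a JSON summary with f_ICCS and d as mean ± SD across
fields of view, TIFF maps and radial correlation profiles.

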