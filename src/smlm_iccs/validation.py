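"""Parameter-recovery benchmarks on simulated ground truth.

Each function runs one seeded trial of a validation scenario — planted
colocalized fraction, planted pair distance, independent channels, planted
drift, uniform localization redundancy, or a spatially structured sample —
and returns the recovered quantity next to its ground truth. The test
suite and the reproduction script both drive these, so the study
conditions live in one place.

Conditions: a 10 x 10 um field rendered at 10 nm/pixel with 50 nm Gaussian
width, 2000 particles per channel, 10 nm localization precision, and a
single localization per emitter (recovery scenarios isolate the estimator
from blinking-multiplicity dispersion, which biases amplitude ratios by
<K>^2/<K^2>; see the methods note). Frame count is irrelevant without
drift — the analysis consumes time-integrated images — so driftless trials
use 1000 frames to keep tables small. The drift scenario uses the full
15,000-frame acquisition with 3 fiducials.
"""

from __future__ import annotations

import numpy as np

from .drift import apply_drift_correction, detect_fiducials, estimate_drift
from .iccs import ICCSResult, compute_iccs
from .registration import Transform2D, masked_iccs, segment_foci, transfer_mask
from .render import RenderedImage, render_image
from .simulate import (SimulationConfig, simulate_confocal, simulate_dataset,
                       simulate_two_population)

__all__ = [
    "recovery_config",
    "render_pair",
    "fraction_recovery_trial",
    "distance_recovery_trial",
    "independence_trial",
    "redundancy_shift_trial",
    "drift_recovery_trial",
    "masked_contrast_trial",
]

EXTENT = (10_000.0, 10_000.0)      # nm
N_PARTICLES = 2000                 # per channel
PIXEL_SIZE = 10.0                  # nm
PSF_WIDTH = 50.0                   # nm (Gaussian sigma)
LOC_PRECISION = 10.0               # nm
MAX_LAG = 32                       # pixels

DRIFT_N_FRAMES = 15_000
DRIFT_STEP_SIGMA = 0.5             # nm/frame random walk
DRIFT_N_FIDUCIALS = 3
DRIFT_CAPTURE_RADIUS = 300.0       # nm; must exceed drift amplitude + noise
DRIFT_SMOOTHING = 101              # frames

FOCUS_CENTERS = np.array([
    [2000.0, 2000.0], [8000.0, 3000.0], [5000.0, 5000.0],
    [2500.0, 7500.0], [7500.0, 8000.0]])
FOCUS_RADIUS = 500.0               # nm


def recovery_config(f_true: float, pair_distance: float, seed: int,
                    **overrides) -> SimulationConfig:
    """Driftless, fiducial-free, single-emission recovery conditions."""
    params = dict(
        extent=EXTENT, n_particles_1=N_PARTICLES, n_particles_2=N_PARTICLES,
        f_true=f_true, pair_distance=pair_distance, n_frames=1000,
        mean_localizations_per_particle=1, emission_model="fixed",
        loc_precision=LOC_PRECISION, n_fiducials=0, seed=seed)
    params.update(overrides)
    return SimulationConfig(**params)


def render_pair(table) -> tuple[RenderedImage, RenderedImage]:
    extent = (0.0, 0.0, EXTENT[0], EXTENT[1])
    img1 = render_image(table, "ch1", pixel_size=PIXEL_SIZE,
                        psf_width=PSF_WIDTH, extent=extent)
    img2 = render_image(table, "ch2", pixel_size=PIXEL_SIZE,
                        psf_width=PSF_WIDTH, extent=extent)
    return img1, img2


def _iccs_for(config: SimulationConfig) -> ICCSResult:
    table, _ = simulate_dataset(config)
    img1, img2 = render_pair(table)
    return compute_iccs(img1, img2, max_lag=MAX_LAG)


def fraction_recovery_trial(f_true: float, seed: int) -> float:
    """Recovered f_ICCS for co-coordinate pairs at planted fraction."""
    return _iccs_for(recovery_config(f_true, 0.0, seed)).f_iccs


def distance_recovery_trial(pair_distance: float, seed: int) -> float:
    """Recovered correlation distance for fully paired channels."""
    return _iccs_for(recovery_config(1.0, pair_distance, seed)).distance_nm


def independence_trial(seed: int) -> float:
    """f_ICCS of two spatially independent channels (negative control)."""
    return _iccs_for(recovery_config(0.0, 0.0, seed)).f_iccs


def redundancy_shift_trial(duplications: int, seed: int) -> float:
    """Change in f_ICCS when every localization is emitted k times over.

    Uniform duplication models degenerate multiple emissions at identical
    coordinates; the pixel-based estimator should be invariant.
    """
    cfg = recovery_config(0.5, 0.0, seed)
    table, _ = simulate_dataset(cfg)
    img1, img2 = render_pair(table)
    base = compute_iccs(img1, img2, max_lag=MAX_LAG).f_iccs

    import pandas as pd
    dup = table.with_data(pd.concat([table.data] * duplications,
                                    ignore_index=True))
    d1, d2 = render_pair(dup)
    return compute_iccs(d1, d2, max_lag=MAX_LAG).f_iccs - base


def drift_recovery_trial(seed: int) -> tuple[float, float]:
    """(RMSE of recovered vs planted drift, residual drift amplitude).

    Random-walk stage drift observed through noisy fiducial tracks; the
    residual amplitude is the maximum of a drift re-estimated on the
    corrected data (should sit below the localization noise floor).
    """
    cfg = SimulationConfig(
        extent=EXTENT, n_particles_1=0, n_particles_2=0,
        n_frames=DRIFT_N_FRAMES, loc_precision=LOC_PRECISION,
        drift_model="random_walk", drift_step_sigma=DRIFT_STEP_SIGMA,
        n_fiducials=DRIFT_N_FIDUCIALS, seed=seed)
    table, truth = simulate_dataset(cfg)
    sub = table.channel("ch1")
    tracks = detect_fiducials(sub, capture_radius=DRIFT_CAPTURE_RADIUS,
                              min_occupancy=0.5)
    traj = estimate_drift(tracks, table.n_frames,
                          smoothing_window=DRIFT_SMOOTHING)
    rmse = float(np.sqrt(np.mean((traj.dx - truth.drift.dx) ** 2
                                 + (traj.dy - truth.drift.dy) ** 2)))
    corrected = apply_drift_correction(sub, traj)
    tracks2 = detect_fiducials(corrected, capture_radius=DRIFT_CAPTURE_RADIUS,
                               min_occupancy=0.5)
    residual = estimate_drift(tracks2, table.n_frames,
                              smoothing_window=DRIFT_SMOOTHING)
    return rmse, residual.amplitude


def masked_contrast_trial(seed: int, f_inside: float = 0.8,
                          f_outside: float = 0.1) -> tuple[float, float]:
    """(global f_ICCS, focus-masked f_ICCS) for a structured sample.

    Particles concentrate high correlation inside synthetic foci; the mask
    is produced end to end (simulated confocal image, Otsu segmentation,
    resampling onto the rendered grid).
    """
    base = recovery_config(0.0, 0.0, seed)
    table, _ = simulate_two_population(
        base, FOCUS_CENTERS, FOCUS_RADIUS,
        f_inside=f_inside, f_outside=f_outside, inside_fraction=0.2)
    img1, img2 = render_pair(table)
    confocal = simulate_confocal(FOCUS_CENTERS, EXTENT,
                                 focus_radius=FOCUS_RADIUS, seed=seed)
    mask = transfer_mask(segment_foci(confocal), Transform2D.identity(), img1)
    global_f = compute_iccs(img1, img2, max_lag=MAX_LAG).f_iccs
    masked_f = masked_iccs(img1, img2, mask, max_lag=MAX_LAG).f_iccs
    return global_f, masked_f
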