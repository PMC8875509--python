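"""Fiducial-based drift correction for localization tables.

Fluorescent nanodiamonds (FNDs) do not blink: unlike single fluorophores,
which are ON in a tiny fraction of frames, a fiducial produces a
localization in (nearly) every recorded frame at almost the same position.
Detection therefore pools all localizations, clusters them spatially at a
capture radius, and keeps clusters whose frame occupancy exceeds a
threshold no blinking fluorophore can reach.

The stage drift at frame f is the mean over fiducial tracks of the track's
displacement from its frame-0 position; sparse (keyframe-sampled) tracks
are linearly interpolated, and an optional moving average suppresses
per-frame localization noise. Correction subtracts the trajectory from
every event; fiducial-containing regions are then excised from the
molecular data before correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .exceptions import ConfigurationError, DriftEstimationError
from .io import LocalizationTable

__all__ = [
    "FiducialTrack",
    "DriftTrajectory",
    "detect_fiducials",
    "estimate_drift",
    "apply_drift_correction",
    "exclude_fiducial_regions",
    "write_drift",
    "read_drift",
]

DEFAULT_CAPTURE_RADIUS = 100.0   # nm; comfortably above the 40 nm FND size
DEFAULT_MIN_OCCUPANCY = 0.5      # blinking duty cycles are far below this
DEFAULT_EXCLUSION_RADIUS = 150.0  # nm; FND size plus rendering width


@dataclass
class FiducialTrack:
    """Per-frame centroid positions of one persistent emitter."""

    id: int
    frames: np.ndarray    # strictly increasing frame indices with a detection
    x: np.ndarray         # nm, per listed frame
    y: np.ndarray
    occupancy: float      # fraction of reference frames with a detection

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ConfigurationError("fiducial track without positions")
        if np.any(np.diff(self.frames) <= 0):
            raise ConfigurationError("track frames must be strictly increasing")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ConfigurationError("occupancy outside [0, 1]")

    @property
    def mean_position(self) -> tuple[float, float]:
        return float(self.x.mean()), float(self.y.mean())


@dataclass
class DriftTrajectory:
    """Per-frame displacement (nm) relative to frame 0."""

    dx: np.ndarray
    dy: np.ndarray
    n_frames: int = 0

    def __post_init__(self):
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.n_frames <= 0:
            self.n_frames = len(self.dx)
        if len(self.dx) != self.n_frames or len(self.dy) != self.n_frames:
            raise ConfigurationError("dx/dy length must equal n_frames")
        if not (np.isfinite(self.dx).all() and np.isfinite(self.dy).all()):
            raise ConfigurationError("non-finite drift values")
        if self.n_frames and (self.dx[0] != 0 or self.dy[0] != 0):
            raise ConfigurationError("drift must be anchored to 0 at frame 0")

    @property
    def amplitude(self) -> float:
        """Maximum displacement magnitude over the trajectory, nm."""
        return float(np.hypot(self.dx, self.dy).max())


def detect_fiducials(table: LocalizationTable,
                     capture_radius: float = DEFAULT_CAPTURE_RADIUS,
                     min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
                     reference_frames: np.ndarray | None = None
                     ) -> list[FiducialTrack]:
    """Identify persistent emitters by spatial clustering plus occupancy.

    All localizations (all frames pooled) are hashed onto a grid of cell
    size ``capture_radius``; dense cells seed clusters whose centroids are
    refined, and a cluster qualifies as a fiducial iff the fraction of
    reference frames containing at least one member is >= ``min_occupancy``.

    ``reference_frames`` lists the frames in which the emitter could have
    been recorded (e.g. keyframes under selective excitation); default is
    every frame of the acquisition.

    Returns a list of tracks with per-frame centroid positions; empty when
    nothing passes the threshold.
    """
    if capture_radius <= 0:
        raise ConfigurationError("capture_radius must be positive")
    if not 0 < min_occupancy <= 1:
        raise ConfigurationError("min_occupancy must be in (0, 1]")
    if len(table) == 0:
        return []

    if reference_frames is None:
        n_ref = max(table.n_frames, 1)
    else:
        n_ref = len(np.unique(reference_frames))
    min_hits = min_occupancy * n_ref

    x, y, frames = table.x, table.y, table.frames
    gx = np.floor(x / capture_radius).astype(np.int64)
    gy = np.floor(y / capture_radius).astype(np.int64)
    cells = pd.DataFrame({"gx": gx, "gy": gy, "i": np.arange(len(x))})
    counts = cells.groupby(["gx", "gy"], sort=False).size()

    # candidate cells: a fiducial's events fall in <= 4 adjacent cells, so
    # its densest cell holds at least a quarter of them
    cand = counts[counts.to_numpy() >= max(1.0, min_hits / 4.0)]
    if len(cand) == 0:
        return []

    cell_index = {k: v.to_numpy() for k, v in cells.groupby(["gx", "gy"], sort=False)["i"]}

    def members_near(cx: float, cy: float) -> np.ndarray:
        cgx, cgy = int(np.floor(cx / capture_radius)), int(np.floor(cy / capture_radius))
        idx = []
        for dgx in (-1, 0, 1):
            for dgy in (-1, 0, 1):
                idx.append(cell_index.get((cgx + dgx, cgy + dgy)))
        idx = np.concatenate([a for a in idx if a is not None]) if any(
            a is not None for a in idx) else np.empty(0, dtype=int)
        if len(idx) == 0:
            return idx
        d2 = (x[idx] - cx) ** 2 + (y[idx] - cy) ** 2
        return idx[d2 <= capture_radius**2]

    tracks: list[FiducialTrack] = []
    used_centroids: list[tuple[float, float]] = []
    order = cand.sort_values(ascending=False).index
    for key in order:
        seed = cell_index[key]
        cx, cy = float(x[seed].mean()), float(y[seed].mean())
        for _ in range(3):  # centroid refinement at the capture radius
            m = members_near(cx, cy)
            if len(m) == 0:
                break
            cx, cy = float(x[m].mean()), float(y[m].mean())
        if len(m) == 0:
            continue
        if any((cx - ux) ** 2 + (cy - uy) ** 2 < capture_radius**2
               for ux, uy in used_centroids):
            continue  # same fiducial reached from an adjacent cell
        member_frames = frames[m]
        if len(np.unique(member_frames)) < min_hits:
            continue
        used_centroids.append((cx, cy))
        sub = pd.DataFrame({"f": member_frames, "x": x[m], "y": y[m]})
        per_frame = sub.groupby("f").mean()
        occ = len(per_frame) / n_ref
        tracks.append(FiducialTrack(
            id=len(tracks),
            frames=per_frame.index.to_numpy(int),
            x=per_frame["x"].to_numpy(),
            y=per_frame["y"].to_numpy(),
            occupancy=min(occ, 1.0),
        ))
        # a genuine fiducial produces ~1 event per frame; a cluster that
        # swallows a large share of the table with many events per frame
        # signals a capture radius far too large
        if len(m) > 0.2 * len(table) and len(m) > 2 * len(per_frame):
            warnings.warn(
                "a single cluster captured >20% of all localizations; "
                "capture_radius is likely too large", stacklevel=2)

    tracks.sort(key=lambda t: t.mean_position)
    for i, t in enumerate(tracks):
        t.id = i
    return tracks


def estimate_drift(tracks: list[FiducialTrack], n_frames: int,
                   smoothing_window: int | None = None) -> DriftTrajectory:
    """Per-frame drift as the mean of track displacements from frame 0.

    Sparse tracks are linearly interpolated to every frame (held at the
    nearest value outside their span, with a warning). An optional moving
    average of ``smoothing_window`` frames suppresses localization noise;
    the trajectory is re-anchored to zero at frame 0 afterwards.

    Raises
    ------
    DriftEstimationError
        No tracks were supplied; the caller should skip drift correction.
    """
    if len(tracks) == 0:
        raise DriftEstimationError(
            "no fiducial tracks: cannot estimate drift; skip correction")
    if n_frames <= 0:
        raise ConfigurationError("n_frames must be positive")

    all_frames = np.arange(n_frames)
    dxs, dys = [], []
    for t in tracks:
        if t.frames[0] > 0 or t.frames[-1] < n_frames - 1:
            warnings.warn(
                f"track {t.id} does not span all frames; holding nearest value "
                "outside its span", stacklevel=2)
        xi = np.interp(all_frames, t.frames, t.x)  # np.interp holds edges
        yi = np.interp(all_frames, t.frames, t.y)
        dxs.append(xi - xi[0])
        dys.append(yi - yi[0])
    dx = np.mean(dxs, axis=0)
    dy = np.mean(dys, axis=0)

    if smoothing_window and smoothing_window > 1:
        size = min(int(smoothing_window), n_frames)
        # centered moving average with mirrored ends; re-anchoring at the
        # smoothed frame-0 value below then cancels the frame-0
        # localization noise that per-track referencing injects as a
        # constant offset ('nearest' padding with the exact-zero frame-0
        # sample would leave half of it in)
        dx = uniform_filter1d(dx, size=size, mode="mirror")
        dy = uniform_filter1d(dy, size=size, mode="mirror")
    dx = dx - dx[0]
    dy = dy - dy[0]
    return DriftTrajectory(dx=dx, dy=dy, n_frames=n_frames)


def apply_drift_correction(table: LocalizationTable,
                           drift: DriftTrajectory) -> LocalizationTable:
    """Subtract the drift at each event's frame from its coordinates."""
    if len(table) == 0:
        return table.with_data(table.data)
    frames = table.frames
    if frames.max() >= drift.n_frames:
        raise ConfigurationError(
            f"frame {int(frames.max())} beyond drift trajectory "
            f"({drift.n_frames} frames)")
    df = table.data.copy()
    df["x_nm"] = df["x_nm"].to_numpy(float) - drift.dx[frames]
    df["y_nm"] = df["y_nm"].to_numpy(float) - drift.dy[frames]
    return table.with_data(df)


def exclude_fiducial_regions(table: LocalizationTable,
                             tracks: list[FiducialTrack],
                             exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS
                             ) -> tuple[LocalizationTable, int]:
    """Remove events near any fiducial's mean position.

    Returns the filtered table and the number of removed events. An event
    exactly at ``exclusion_radius`` is removed (closed disc).
    """
    if exclusion_radius <= 0:
        raise ConfigurationError("exclusion_radius must be positive")
    if len(tracks) == 0 or len(table) == 0:
        return table.with_data(table.data), 0
    x, y = table.x, table.y
    keep = np.ones(len(table), dtype=bool)
    for t in tracks:
        cx, cy = t.mean_position
        keep &= (x - cx) ** 2 + (y - cy) ** 2 > exclusion_radius**2
    removed = int((~keep).sum())
    out = table.with_data(table.data[keep])
    out.metadata["n_excluded_fiducial_events"] = removed
    return out, removed


def write_drift(drift: DriftTrajectory, path) -> None:
    """Persist a trajectory as delimited text (frame, dx_nm, dy_nm)."""
    pd.DataFrame({
        "frame": np.arange(drift.n_frames),
        "dx_nm": drift.dx,
        "dy_nm": drift.dy,
    }).to_csv(path, index=False, float_format="%.6f")


def read_drift(path) -> DriftTrajectory:
    df = pd.read_csv(path)
    return DriftTrajectory(dx=df["dx_nm"].to_numpy(float),
                           dy=df["dy_nm"].to_numpy(float))
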