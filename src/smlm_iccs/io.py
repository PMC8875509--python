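"""Reading, writing and validating single-molecule localization tables.

The pipeline's native input is a list of localization events, one row per
detected single-molecule emission, as exported by SMLM fitting software.
The native dialect is comma-separated text with the header::

    frame,channel,x_nm,y_nm,photons,precision_nm

Foreign exports (e.g. "x [nm]" columns, 1-based frame numbers, coordinates
in camera pixels) are supported through a :class:`Dialect` mapping.
Coordinates are continuous nanometres in sample space, origin at the
field-of-view corner, y increasing downward (image convention); frames are
0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .exceptions import ConfigurationError, EmptyInputError

__all__ = [
    "Dialect",
    "NATIVE_DIALECT",
    "LocalizationTable",
    "read_localizations",
    "write_localizations",
    "read_grayscale_tiff",
    "write_grayscale_tiff",
]

#: Canonical column order of the in-memory table and the native file format.
COLUMNS = ["frame", "channel", "x_nm", "y_nm", "photons", "precision_nm"]


@dataclass(frozen=True)
class Dialect:
    """Column-mapping specification for delimited localization files.

    Parameters
    ----------
    frame, x, y : str
        Column names holding the frame index and coordinates (required).
    channel, photons, precision : str or None
        Optional column names; ``channel=None`` assigns ``default_channel``
        to every row.
    unit : {"nm", "pixel"}
        Coordinate unit in the file. ``"pixel"`` requires
        ``camera_pixel_size`` (nm per camera pixel) and converts on read.
    one_based_frames : bool
        Set when the file counts frames from 1; internal frames are 0-based.
    delimiter : str
        Field separator.
    """

    frame: str = "frame"
    x: str = "x_nm"
    y: str = "y_nm"
    channel: str | None = "channel"
    photons: str | None = "photons"
    precision: str | None = "precision_nm"
    unit: str = "nm"
    camera_pixel_size: float | None = None
    one_based_frames: bool = False
    delimiter: str = ","
    default_channel: str = "ch1"

    def __post_init__(self):
        if self.unit not in ("nm", "pixel"):
            raise ConfigurationError(f"unknown coordinate unit {self.unit!r}")
        if self.unit == "pixel" and not self.camera_pixel_size:
            raise ConfigurationError(
                "unit='pixel' requires camera_pixel_size (nm per camera pixel)"
            )


NATIVE_DIALECT = Dialect()


@dataclass
class LocalizationTable:
    """Ordered collection of localization events plus acquisition metadata.

    ``data`` holds the canonical columns (``frame``, ``channel``, ``x_nm``,
    ``y_nm`` and, when available, ``photons`` and ``precision_nm``).
    ``n_frames`` is the total number of acquired frames; it may exceed the
    largest frame index present (sparse blinking).
    """

    data: pd.DataFrame
    n_frames: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.data
        for col in ("frame", "channel", "x_nm", "y_nm"):
            if col not in df.columns:
                raise ConfigurationError(f"localization table lacks column {col!r}")
        x = df["x_nm"].to_numpy(float)
        y = df["y_nm"].to_numpy(float)
        if len(df) and not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ConfigurationError("non-finite coordinates in localization table")
        frames = df["frame"].to_numpy()
        if len(df) and frames.min() < 0:
            raise ConfigurationError("negative frame index")
        if self.n_frames <= 0:
            self.n_frames = int(frames.max()) + 1 if len(df) else 0
        elif len(df) and frames.max() >= self.n_frames:
            raise ConfigurationError(
                f"frame index {int(frames.max())} outside [0, {self.n_frames})"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def x(self) -> np.ndarray:
        return self.data["x_nm"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y_nm"].to_numpy(float)

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy(int)

    def channels(self) -> list:
        """Channel labels present, in order of first appearance."""
        return list(dict.fromkeys(self.data["channel"]))

    def channel(self, label) -> "LocalizationTable":
        """Lossless per-channel subset (shares ``n_frames`` and metadata)."""
        sub = self.data[self.data["channel"] == label].reset_index(drop=True)
        return LocalizationTable(sub, n_frames=self.n_frames, metadata=dict(self.metadata))

    def with_data(self, df: pd.DataFrame) -> "LocalizationTable":
        return LocalizationTable(df.reset_index(drop=True), n_frames=self.n_frames,
                                 metadata=dict(self.metadata))

    def sorted_by_frame(self) -> "LocalizationTable":
        return self.with_data(self.data.sort_values("frame", kind="stable"))

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) over all channels, in nm."""
        if not len(self.data):
            raise EmptyInputError("bounding box of an empty table")
        return (float(self.x.min()), float(self.y.min()),
                float(self.x.max()), float(self.y.max()))

    @classmethod
    def from_arrays(cls, frame, x, y, channel, photons=None, precision=None,
                    n_frames=0, metadata=None) -> "LocalizationTable":
        frame = np.asarray(frame, dtype=int)
        cols = {
            "frame": frame,
            "channel": np.broadcast_to(np.asarray(channel, dtype=object), frame.shape).copy()
            if np.ndim(channel) == 0 else np.asarray(channel, dtype=object),
            "x_nm": np.asarray(x, dtype=float),
            "y_nm": np.asarray(y, dtype=float),
        }
        if photons is not None:
            cols["photons"] = np.asarray(photons, dtype=float)
        if precision is not None:
            cols["precision_nm"] = np.asarray(precision, dtype=float)
        return cls(pd.DataFrame(cols), n_frames=n_frames, metadata=metadata or {})


def read_localizations(path, dialect: Dialect = NATIVE_DIALECT,
                       n_frames: int = 0) -> LocalizationTable:
    """Read a delimited localization file into a :class:`LocalizationTable`.

    Coordinates are converted to nm according to the dialect; frames are
    shifted to 0-based if the dialect declares 1-based input. Rows with
    non-numeric coordinates or frames are dropped with a warning naming the
    first offending line; the count is stored in
    ``metadata["n_malformed_rows"]``.

    Raises
    ------
    ConfigurationError
        If a required column is missing from the header.
    EmptyInputError
        If the file has no data rows.
    """
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty localization file") from None
    raw.columns = [str(c).strip() for c in raw.columns]

    for role, name in (("frame", dialect.frame), ("x", dialect.x), ("y", dialect.y)):
        if name not in raw.columns:
            raise ConfigurationError(
                f"{path}: required column {name!r} (role: {role}) not found; "
                f"available: {list(raw.columns)}"
            )
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no localization records")

    frame = pd.to_numeric(raw[dialect.frame], errors="coerce")
    x = pd.to_numeric(raw[dialect.x], errors="coerce")
    y = pd.to_numeric(raw[dialect.y], errors="coerce")
    bad = frame.isna() | x.isna() | y.isna()
    n_bad = int(bad.sum())
    if n_bad:
        first = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: header line plus 1-based numbering
        warnings.warn(
            f"{path}: dropped {n_bad} malformed row(s), first at line {first + 2}",
            stacklevel=2,
        )
        keep = ~bad
        raw, frame, x, y = raw[keep], frame[keep], x[keep], y[keep]
        if len(raw) == 0:
            raise EmptyInputError(f"{path}: all rows malformed")

    scale = dialect.camera_pixel_size if dialect.unit == "pixel" else 1.0
    frame_vals = frame.to_numpy(float).astype(int)
    if dialect.one_based_frames:
        frame_vals = frame_vals - 1

    if dialect.channel and dialect.channel in raw.columns:
        channel = raw[dialect.channel].astype(str).str.strip().to_numpy(object)
    else:
        channel = np.full(len(raw), dialect.default_channel, dtype=object)

    photons = precision = None
    if dialect.photons and dialect.photons in raw.columns:
        photons = pd.to_numeric(raw[dialect.photons], errors="coerce").to_numpy(float)
    if dialect.precision and dialect.precision in raw.columns:
        precision = pd.to_numeric(raw[dialect.precision], errors="coerce").to_numpy(float)

    table = LocalizationTable.from_arrays(
        frame_vals, x.to_numpy(float) * scale, y.to_numpy(float) * scale,
        channel, photons=photons, precision=precision, n_frames=n_frames,
        metadata={"source": str(path), "n_malformed_rows": n_bad},
    )
    return table


def write_localizations(table: LocalizationTable, path) -> None:
    """Write a table in the native comma-separated dialect.

    Coordinates are printed with six decimals (1e-6 nm round-trip fidelity).
    An empty table produces a header-only file.
    """
    cols = [c for c in COLUMNS if c in table.data.columns]
    out = table.data[cols]
    out.to_csv(path, index=False, float_format="%.6f")


def read_grayscale_tiff(path) -> np.ndarray:
    """Read a single-plane grayscale TIFF as float64."""
    img = tifffile.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ConfigurationError(
            f"{path}: expected a single-plane grayscale image, got shape {img.shape}"
        )
    return img.astype(np.float64)


def write_grayscale_tiff(path, pixels: np.ndarray) -> None:
    """Write a 2D array as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(pixels, dtype=np.float32))
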