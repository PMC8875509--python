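"""Correlative confocal-SMLM registration and mask-restricted ICCS.

Confocal images (diffraction-limited, ~70 nm pixels) and SMLM rendered
images (typically 10 nm pixels) live in different coordinate frames. The
same fiducial nanodiamonds visible in both modalities provide matched
landmarks from which a 2D transform (translation, similarity or affine,
in physical nm coordinates) is estimated by least squares. Masks segmented
on the confocal image (e.g. gammaH2A.X foci marking DNA damage) are then
resampled onto the SMLM grid and used to restrict the ICCS analysis to the
regions they cover.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.transform import estimate_transform

from .exceptions import ConditioningError, ConfigurationError, DegenerateInputError
from .iccs import ICCSResult, compute_iccs
from .render import RenderedImage

__all__ = [
    "Transform2D",
    "Mask",
    "estimate_transform_2d",
    "match_landmarks",
    "segment_foci",
    "transfer_mask",
    "masked_iccs",
]

DEFAULT_CONFOCAL_PIXEL_SIZE = 70.0  # nm
DEFAULT_MIN_AREA = 20               # confocal pixels

_MIN_POINTS = {"translation": 1, "similarity": 2, "affine": 3}


@dataclass
class Transform2D:
    """Affine-family mapping (x, y) nm -> (x, y) nm between modalities."""

    model: str                 # "translation" | "similarity" | "affine"
    matrix: np.ndarray         # 2x3: [A | t]
    rms_residual: float = 0.0  # nm, over the landmarks used for estimation

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ConditioningError("transform linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "Transform2D":
        a = np.linalg.inv(self.matrix[:, :2])
        t = -a @ self.matrix[:, 2]
        return Transform2D(self.model, np.column_stack([a, t]),
                           rms_residual=self.rms_residual)

    def to_dict(self) -> dict:
        return {"model": self.model, "matrix": self.matrix.tolist(),
                "rms_residual_nm": self.rms_residual}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "Transform2D":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["model"], np.asarray(d["matrix"]),
                   rms_residual=d.get("rms_residual_nm", 0.0))

    @classmethod
    def identity(cls, model: str = "translation") -> "Transform2D":
        return cls(model, np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))


@dataclass
class Mask:
    """Binary pixel mask with the same physical geometry as an image grid."""

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ConfigurationError("mask must be a 2D grid")

    @property
    def n_set(self) -> int:
        return int(self.pixels.sum())

    @property
    def coverage(self) -> float:
        return float(self.pixels.mean())

    def matches_grid(self, img: RenderedImage) -> bool:
        return (self.pixels.shape == img.pixels.shape
                and self.pixel_size == img.pixel_size
                and tuple(self.origin) == tuple(img.origin))


def estimate_transform_2d(src_points, dst_points, model: str = "similarity"
                          ) -> Transform2D:
    """Least-squares transform from matched landmark pairs (nm -> nm).

    Requires >= 1 pair (translation), >= 2 (similarity), >= 3 (affine).
    The RMS residual over the landmarks is attached to the result.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ConfigurationError("matched point lists must be (n, 2) and equal length")
    if model not in _MIN_POINTS:
        raise ConfigurationError(f"unknown transform model {model!r}")
    if len(src) < _MIN_POINTS[model]:
        raise ConfigurationError(
            f"{model} transform needs >= {_MIN_POINTS[model]} point pairs")

    if model == "translation":
        t = (dst - src).mean(axis=0)
        matrix = np.column_stack([np.eye(2), t])
    else:
        centered = src - src.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if model == "affine" and (len(sv) < 2 or sv[1] <= 1e-9 * max(sv[0], 1.0)):
            raise ConditioningError("collinear landmarks cannot fix an affine map")
        if sv[0] <= 1e-12:
            raise ConditioningError("coincident landmarks")
        tf = estimate_transform(model, src, dst)
        params = tf.params
        if not np.all(np.isfinite(params)) or abs(np.linalg.det(params[:2, :2])) < 1e-12:
            raise ConditioningError(
                f"degenerate landmark geometry for {model} transform")
        matrix = params[:2, :]

    out = Transform2D(model, matrix)
    res = out.apply(src) - dst
    out.rms_residual = float(np.sqrt(np.mean(np.sum(res**2, axis=1)))) if len(src) else 0.0
    return out


def match_landmarks(src_points, dst_points, max_distance: float = np.inf
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pair unordered landmark sets by mutual nearest neighbour.

    A coarse translation (difference of centroids) is removed before
    matching, which is robust for the few, well-separated fiducials of a
    typical field of view. Returns the matched (src, dst) coordinate arrays.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if len(src) == 0 or len(dst) == 0:
        return src[:0], dst[:0]
    shift = dst.mean(axis=0) - src.mean(axis=0)
    moved = src + shift
    tree_d = cKDTree(dst)
    tree_s = cKDTree(moved)
    d_sd, nn_sd = tree_d.query(moved)
    _, nn_ds = tree_s.query(dst)
    pairs = [(i, j) for i, (j, dist) in enumerate(zip(nn_sd, d_sd))
             if nn_ds[j] == i and dist <= max_distance]
    if not pairs:
        return src[:0], dst[:0]
    si, di = map(np.asarray, zip(*pairs))
    return src[si], dst[di]


def segment_foci(image: np.ndarray, min_area: int = DEFAULT_MIN_AREA,
                 threshold_method: str = "otsu",
                 pixel_size: float = DEFAULT_CONFOCAL_PIXEL_SIZE,
                 origin: tuple[float, float] = (0.0, 0.0)) -> Mask:
    """Segment bright foci in a grayscale image into a binary mask.

    Global threshold (Otsu by default, or "mean"), connected components,
    then removal of components below ``min_area`` pixels. Components
    touching the border are retained.
    """
    if isinstance(image, RenderedImage):
        pixel_size = image.pixel_size
        origin = image.origin
        image = image.pixels
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ConfigurationError("expected a single-channel 2D image")
    if np.ptp(img) == 0:
        raise DegenerateInputError("constant image cannot be thresholded")

    if threshold_method == "otsu":
        thr = threshold_otsu(img)
    elif threshold_method == "mean":
        thr = img.mean()
    else:
        raise ConfigurationError(f"unknown threshold method {threshold_method!r}")

    binary = img > thr
    labels = measure.label(binary, connectivity=2)
    out = np.zeros_like(binary)
    n_kept = 0
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            out[labels == region.label] = True
            n_kept += 1
    if n_kept == 0:
        warnings.warn("no components survived min_area filtering; empty mask",
                      stacklevel=2)
    return Mask(out, pixel_size=pixel_size, origin=origin)


def transfer_mask(mask: Mask, transform: Transform2D,
                  target: RenderedImage) -> Mask:
    """Resample a mask into the geometry of a target image grid.

    ``transform`` maps mask-frame nm coordinates into target-frame nm
    coordinates. Each target pixel center is pulled back through the
    inverse transform and sampled from the mask by nearest neighbour.
    """
    inv = transform.inverse()
    ny, nx = target.pixels.shape
    tx0, ty0 = target.origin
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    centers = np.column_stack([
        tx0 + (jj.ravel() + 0.5) * target.pixel_size,
        ty0 + (ii.ravel() + 0.5) * target.pixel_size,
    ])
    back = inv.apply(centers)
    mx0, my0 = mask.origin
    col = np.floor((back[:, 0] - mx0) / mask.pixel_size).astype(int)
    row = np.floor((back[:, 1] - my0) / mask.pixel_size).astype(int)
    mny, mnx = mask.pixels.shape
    inside = (row >= 0) & (row < mny) & (col >= 0) & (col < mnx)
    vals = np.zeros(len(centers), dtype=bool)
    vals[inside] = mask.pixels[row[inside], col[inside]]
    out = vals.reshape(ny, nx)
    if mask.n_set and not out.any():
        warnings.warn("transform maps the mask entirely outside the target grid",
                      stacklevel=2)
    return Mask(out, pixel_size=target.pixel_size, origin=target.origin)


def masked_iccs(img_1: RenderedImage, img_2: RenderedImage, mask: Mask,
                **params) -> ICCSResult:
    """ICCS restricted to a mask on the rendered grid.

    Delegates to :func:`smlm_iccs.iccs.compute_iccs` with the mask as ROI;
    the result records the mask coverage fraction in its flags-free
    ``roi_area`` plus ``mask_coverage`` attribute on the returned object.
    """
    if not mask.matches_grid(img_1):
        raise ConfigurationError("mask geometry does not match the image grid")
    if mask.n_set == 0:
        raise DegenerateInputError("empty mask")
    result = compute_iccs(img_1, img_2, roi=mask.pixels, **params)
    result.mask_coverage = mask.coverage
    return result
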