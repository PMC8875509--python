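"""Image cross-correlation spectroscopy (ICCS) on rendered SMLM images.

The spatial correlation of two channels a, b over a region of interest is

    G_ab(xi, eta) = < dI_a(x, y) * dI_b(x + xi, y + eta) > / (<I_a> <I_b>)

with fluctuations dI = I - <I> and all averages over ROI pixels. The
surfaces are evaluated by FFT with masked normalization: fluctuations are
zeroed outside the ROI, the raw lag products are divided by the per-lag
count of overlapping ROI pixel pairs (itself an FFT correlation of the
mask), so edges and arbitrary ROI shapes are handled without periodic
wrap-around.

Each surface is fitted with an isotropic Gaussian
``G(xi, eta) = G0 * exp(-(xi^2 + eta^2) / w^2) + Ginf`` where ``w`` is the
e^-1 radius in lag space. For images rendered with Gaussian sigma, the
autocorrelation width is w_auto = 2*sigma.

Colocalization coefficients follow the ICCS amplitude formalism:
M1 = G0_cross / G0_auto2 (fraction of channel-1 particles with a channel-2
partner), M2 = G0_cross / G0_auto1, and the colocalized fraction f_ICCS is
their arithmetic mean. The correlation distance is recovered from the
broadening of the cross-correlation,
d = sqrt(max(0, w_cross^2 - (w_auto1^2 + w_auto2^2)/2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.special import i0e

from .exceptions import ConfigurationError, DegenerateInputError, InsufficientROIError
from .render import RenderedImage

__all__ = [
    "CorrelationSurface",
    "CorrelationFit",
    "ICCSResult",
    "ColocalizationMap",
    "compute_correlation",
    "correlation_direct",
    "fit_correlation",
    "compute_iccs",
    "local_iccs",
    "radial_profile",
    "predicted_distance_estimate",
]

DEFAULT_MAX_LAG = 32  # pixels (320 nm at 10 nm/pixel)


@dataclass
class CorrelationSurface:
    """2D correlation values over integer pixel lags in [-L, L]^2."""

    values: np.ndarray          # (2L+1, 2L+1); [L, L] is zero lag
    pixel_size: float           # nm
    kind: str                   # "auto-1" | "auto-2" | "cross"
    n_pixels_used: np.ndarray   # per-lag count of contributing pixel pairs

    @property
    def max_lag(self) -> int:
        return self.values.shape[0] // 2

    def lag_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(xi, eta) integer pixel-lag grids matching ``values``."""
        L = self.max_lag
        lag = np.arange(-L, L + 1)
        xi, eta = np.meshgrid(lag, lag)
        return xi, eta

    @property
    def zero_lag_value(self) -> float:
        L = self.max_lag
        return float(self.values[L, L])


@dataclass
class CorrelationFit:
    """Gaussian-model parameters fitted to a correlation surface."""

    g0: float            # amplitude, dimensionless
    width_nm: float      # e^-1 radius of the fitted Gaussian, nm
    offset: float        # long-range baseline G_inf
    residual: float      # RMS of fit residuals
    converged: bool
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "g0": self.g0, "width_nm": self.width_nm, "offset": self.offset,
            "residual": self.residual, "converged": self.converged,
            "n_points": self.n_points,
        }


@dataclass
class ICCSResult:
    """Colocalized fraction, correlation distance and fit diagnostics."""

    m1: float                       # G0_cross / G0_auto2
    m2: float                       # G0_cross / G0_auto1
    f_iccs: float                   # (m1 + m2) / 2
    distance_nm: float              # >= 0, nan when undefined
    fits: dict = field(default_factory=dict)   # "auto-1", "auto-2", "cross"
    roi_area: int = 0               # ROI pixels
    valid: bool = True
    flags: list = field(default_factory=list)
    surfaces: dict | None = None

    @property
    def f_iccs_clamped(self) -> float:
        """Convenience value of f_ICCS clipped to [0, 1]."""
        return float(np.clip(self.f_iccs, 0.0, 1.0)) if np.isfinite(self.f_iccs) else np.nan

    def to_dict(self) -> dict:
        return {
            "m1": self.m1, "m2": self.m2,
            "f_iccs": self.f_iccs, "f_iccs_clamped": self.f_iccs_clamped,
            "distance_nm": self.distance_nm, "roi_area": self.roi_area,
            "valid": self.valid, "flags": list(self.flags),
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
        }


@dataclass
class ColocalizationMap:
    """Local f_ICCS / distance maps over tiled subregions."""

    f_map: np.ndarray      # NaN where invalid
    d_map: np.ndarray
    valid: np.ndarray      # bool
    window: int
    step: int
    center_rows: np.ndarray   # pixel row of each map row's subregion center
    center_cols: np.ndarray
    pixel_size: float


def _check_pair(img_a: RenderedImage, img_b: RenderedImage) -> None:
    if img_a.pixels.shape != img_b.pixels.shape:
        raise ConfigurationError("images must share grid dimensions")
    if img_a.pixel_size != img_b.pixel_size:
        raise ConfigurationError("images must share pixel size")


def _xcorr_full(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Linear cross-correlation c[k] = sum_n a[n] b[n+k] via FFT.

    Lag (0, 0) sits at index (na_rows - 1, na_cols - 1) of the full output.
    """
    return signal.fftconvolve(b, a[::-1, ::-1], mode="full")


def compute_correlation(img_a: RenderedImage, img_b: RenderedImage,
                        roi: np.ndarray | None = None,
                        max_lag: int = DEFAULT_MAX_LAG) -> CorrelationSurface:
    """FFT-based masked spatial correlation of two images on a shared grid.

    ``roi`` is an optional boolean mask (same shape); statistics are taken
    over ROI pixels only. Lags with no overlapping ROI pixel pairs are NaN.
    The auto-correlation is the ``img_a is img_b`` case.

    Raises
    ------
    InsufficientROIError
        Fewer ROI pixels than the (2*max_lag+1)^2 lag window.
    DegenerateInputError
        Constant-zero image over the ROI (mean zero; unnormalizable).
    """
    _check_pair(img_a, img_b)
    A, B = img_a.pixels, img_b.pixels
    if roi is None:
        mask = np.ones(A.shape, dtype=bool)
    else:
        mask = np.asarray(roi).astype(bool)
        if mask.shape != A.shape:
            raise ConfigurationError("ROI mask must match image dimensions")
    n_roi = int(mask.sum())
    if n_roi < (2 * max_lag + 1) ** 2:
        raise InsufficientROIError(
            f"ROI of {n_roi} pixels smaller than the (2*{max_lag}+1)^2 lag window"
        )

    mean_a = A[mask].mean()
    mean_b = B[mask].mean()
    if mean_a == 0 or mean_b == 0:
        raise DegenerateInputError("image mean over ROI is zero")

    m = mask.astype(float)
    da = np.where(mask, A - mean_a, 0.0)
    db = np.where(mask, B - mean_b, 0.0)

    ny, nx = A.shape
    c0, c1 = ny - 1, nx - 1
    sl = (slice(c0 - max_lag, c0 + max_lag + 1),
          slice(c1 - max_lag, c1 + max_lag + 1))
    num = _xcorr_full(da, db)[sl]
    cnt = np.rint(_xcorr_full(m, m)[sl])

    values = np.full(num.shape, np.nan)
    ok = cnt > 0
    values[ok] = num[ok] / (cnt[ok] * mean_a * mean_b)

    kind = "auto" if img_a is img_b or np.array_equal(A, B) else "cross"
    return CorrelationSurface(values=values, pixel_size=img_a.pixel_size,
                              kind=kind, n_pixels_used=cnt.astype(int))


def correlation_direct(img_a: RenderedImage, img_b: RenderedImage,
                       roi: np.ndarray | None = None,
                       max_lag: int = 5) -> CorrelationSurface:
    """Reference evaluation of the correlation definition, lag by lag.

    Independent of the FFT path: for every integer lag the overlapping pixel
    pairs are enumerated by array shifts and averaged directly. Quadratic in
    the lag window; intended for validation on small images.
    """
    _check_pair(img_a, img_b)
    A, B = img_a.pixels, img_b.pixels
    mask = np.ones(A.shape, bool) if roi is None else np.asarray(roi).astype(bool)
    mean_a = A[mask].mean()
    mean_b = B[mask].mean()
    if mean_a == 0 or mean_b == 0:
        raise DegenerateInputError("image mean over ROI is zero")
    da = A - mean_a
    db = B - mean_b
    ny, nx = A.shape
    size = 2 * max_lag + 1
    values = np.full((size, size), np.nan)
    counts = np.zeros((size, size), dtype=int)
    for eta in range(-max_lag, max_lag + 1):
        for xi in range(-max_lag, max_lag + 1):
            y0, y1 = max(0, -eta), min(ny, ny - eta)
            x0, x1 = max(0, -xi), min(nx, nx - xi)
            if y1 <= y0 or x1 <= x0:
                continue
            m_pair = mask[y0:y1, x0:x1] & mask[y0 + eta:y1 + eta, x0 + xi:x1 + xi]
            n = int(m_pair.sum())
            counts[eta + max_lag, xi + max_lag] = n
            if n:
                prod = da[y0:y1, x0:x1] * db[y0 + eta:y1 + eta, x0 + xi:x1 + xi]
                values[eta + max_lag, xi + max_lag] = (
                    prod[m_pair].sum() / (n * mean_a * mean_b))
    return CorrelationSurface(values=values, pixel_size=img_a.pixel_size,
                              kind="direct", n_pixels_used=counts)


def _gauss2d(params, r2):
    g0, w, ginf = params
    return g0 * np.exp(-r2 / w**2) + ginf


def fit_correlation(surface: CorrelationSurface,
                    fit_radius: int | None = None,
                    include_zero_lag: bool = True,
                    max_width: float | None = None) -> CorrelationFit:
    """Least-squares Gaussian fit of a correlation surface.

    Fits ``G0 * exp(-(xi^2+eta^2)/w^2) + Ginf`` over the full 2D disc of
    lags with radius <= ``fit_radius`` (default: all lags). Initial values:
    Ginf from the median of the rim lags, G0 from the zero-lag excess,
    w = 2 pixels. Never raises on non-convergence; the ``converged`` flag
    reports the optimizer status. A negative fitted amplitude is retained
    (it signals anticorrelation or noise). ``max_width`` (pixels) caps the
    fitted e^-1 radius; callers use it to hold a noisy cross-correlation
    fit at a physically plausible scale.
    """
    L = surface.max_lag
    if fit_radius is None:
        fit_radius = L
    fit_radius = min(fit_radius, L)
    xi, eta = surface.lag_grids()
    r2 = (xi**2 + eta**2).astype(float)
    r = np.sqrt(r2)
    sel = (r <= fit_radius) & np.isfinite(surface.values) & (surface.n_pixels_used > 0)
    if not include_zero_lag:
        sel &= r2 > 0
    n_points = int(sel.sum())
    if n_points < 8:
        raise InsufficientROIError(
            f"only {n_points} usable lag points within fit radius {fit_radius}")

    g = surface.values[sel]
    rr2 = r2[sel]
    rim = (r >= fit_radius - 1.0) & sel
    ginf0 = float(np.median(surface.values[rim])) if rim.any() else 0.0
    g00 = surface.zero_lag_value - ginf0
    if not np.isfinite(g00):
        g00 = float(np.nanmax(g)) - ginf0
    w_hi = 10.0 * max(fit_radius, 1) if max_width is None else float(max_width)
    p0 = np.array([g00, min(2.0, 0.5 * w_hi), ginf0])

    def resid(p):
        return _gauss2d(p, rr2) - g

    try:
        res = optimize.least_squares(
            resid, p0,
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, w_hi, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        converged = bool(res.success)
        g0, w, ginf = res.x
        rms = float(np.sqrt(np.mean(res.fun**2)))
    except Exception:
        converged, g0, w, ginf, rms = False, np.nan, np.nan, np.nan, np.nan

    return CorrelationFit(g0=float(g0), width_nm=float(w * surface.pixel_size),
                          offset=float(ginf), residual=rms, converged=converged,
                          n_points=n_points)


def _distance_from_widths(w_cross: float, w_auto1: float, w_auto2: float
                          ) -> tuple[float, bool]:
    """Broadening quadrature; returns (distance_nm, floored_to_zero)."""
    excess = w_cross**2 - 0.5 * (w_auto1**2 + w_auto2**2)
    if excess <= 0:
        return 0.0, True
    return float(np.sqrt(excess)), False


def compute_iccs(img_1: RenderedImage, img_2: RenderedImage,
                 roi: np.ndarray | None = None,
                 max_lag: int = DEFAULT_MAX_LAG,
                 fit_radius: int | None = None,
                 include_zero_lag: bool = True,
                 keep_surfaces: bool = False) -> ICCSResult:
    """Full ICCS analysis of an image pair: three surfaces, fits, f and d.

    Returns an :class:`ICCSResult`; ``valid`` is False when an
    autocorrelation fit fails or has non-positive amplitude. A failed
    cross-correlation fit with healthy autocorrelations yields f_ICCS = 0
    (no detectable correlation) with a flag.
    """
    _check_pair(img_1, img_2)
    auto1_s = compute_correlation(img_1, img_1, roi=roi, max_lag=max_lag)
    auto1_s.kind = "auto-1"
    auto2_s = compute_correlation(img_2, img_2, roi=roi, max_lag=max_lag)
    auto2_s.kind = "auto-2"
    cross_s = compute_correlation(img_1, img_2, roi=roi, max_lag=max_lag)
    cross_s.kind = "cross"

    fits = {s.kind: fit_correlation(s, fit_radius=fit_radius,
                                    include_zero_lag=include_zero_lag)
            for s in (auto1_s, auto2_s, cross_s)}
    a1, a2, cx = fits["auto-1"], fits["auto-2"], fits["cross"]

    # a cross width far beyond the pooled auto width is not a
    # colocalization broadening (w_cross^2 = w_auto^2 + d^2 with d of PSF
    # scale); on noise the free fit can latch onto long-range structure
    # with an inflated amplitude, so refit at a plausible scale
    width_cap_flag = False
    if a1.converged and a2.converged and cx.converged:
        pooled = np.sqrt(0.5 * (a1.width_nm**2 + a2.width_nm**2))
        if cx.width_nm > 3.0 * pooled > 0:
            cx = fit_correlation(cross_s, fit_radius=fit_radius,
                                 include_zero_lag=include_zero_lag,
                                 max_width=3.0 * pooled / cross_s.pixel_size)
            fits["cross"] = cx
            width_cap_flag = True
    roi_area = int(np.sum(roi)) if roi is not None else int(np.prod(img_1.pixels.shape))

    flags: list[str] = []
    valid = True
    if not (a1.converged and a2.converged):
        flags.append("autocorrelation fit failed")
        valid = False
    elif a1.g0 <= 0 or a2.g0 <= 0:
        flags.append("non-positive autocorrelation amplitude")
        valid = False

    if not valid:
        result = ICCSResult(m1=np.nan, m2=np.nan, f_iccs=np.nan,
                            distance_nm=np.nan, fits=fits, roi_area=roi_area,
                            valid=False, flags=flags)
    elif not cx.converged:
        flags.append("cross-correlation fit failed; reporting f_ICCS = 0")
        result = ICCSResult(m1=0.0, m2=0.0, f_iccs=0.0, distance_nm=np.nan,
                            fits=fits, roi_area=roi_area, valid=False, flags=flags)
    else:
        m1 = cx.g0 / a2.g0
        m2 = cx.g0 / a1.g0
        f = 0.5 * (m1 + m2)
        d, floored = _distance_from_widths(cx.width_nm, a1.width_nm, a2.width_nm)
        if width_cap_flag:
            flags.append("cross width capped at 3x pooled auto width")
        if floored:
            flags.append("cross width below pooled auto width; distance floored to 0")
        if cx.g0 < 0:
            flags.append("negative cross-correlation amplitude")
        result = ICCSResult(m1=float(m1), m2=float(m2), f_iccs=float(f),
                            distance_nm=d, fits=fits, roi_area=roi_area,
                            valid=True, flags=flags)
    if keep_surfaces:
        result.surfaces = {"auto-1": auto1_s, "auto-2": auto2_s, "cross": cross_s}
    return result


def local_iccs(img_1: RenderedImage, img_2: RenderedImage,
               window: int = 69, step: int | None = None,
               roi: np.ndarray | None = None,
               max_lag: int = 16, fit_radius: int | None = None,
               min_coverage: float = 0.25) -> ColocalizationMap:
    """Map f_ICCS and d over square subregions tiling the image.

    The analysis window (default 69 pixels, odd) slides with the given step
    (default window // 2); each tile is analysed with :func:`compute_iccs`
    restricted to the tile. Tiles with ROI coverage below ``min_coverage``
    or failed fits are marked invalid (NaN in the maps).
    """
    _check_pair(img_1, img_2)
    ny, nx = img_1.pixels.shape
    if window % 2 == 0:
        raise ConfigurationError("window must be odd")
    if window > ny or window > nx:
        raise ConfigurationError(f"window {window} exceeds image size {img_1.pixels.shape}")
    if step is None:
        step = max(1, window // 2)
    mask = np.ones((ny, nx), bool) if roi is None else np.asarray(roi).astype(bool)

    row_starts = np.arange(0, ny - window + 1, step)
    col_starts = np.arange(0, nx - window + 1, step)
    f_map = np.full((len(row_starts), len(col_starts)), np.nan)
    d_map = np.full_like(f_map, np.nan)
    valid = np.zeros(f_map.shape, dtype=bool)

    for i, r0 in enumerate(row_starts):
        for j, c0 in enumerate(col_starts):
            tile = (slice(r0, r0 + window), slice(c0, c0 + window))
            sub_mask = mask[tile]
            if sub_mask.mean() < min_coverage:
                continue
            x0, y0 = img_1.origin
            origin = (x0 + c0 * img_1.pixel_size, y0 + r0 * img_1.pixel_size)
            sub1 = RenderedImage(img_1.pixels[tile], img_1.pixel_size, origin,
                                 img_1.psf_width)
            sub2 = RenderedImage(img_2.pixels[tile], img_2.pixel_size, origin,
                                 img_2.psf_width)
            try:
                res = compute_iccs(sub1, sub2, roi=sub_mask, max_lag=max_lag,
                                   fit_radius=fit_radius)
            except (DegenerateInputError, InsufficientROIError):
                continue
            if res.valid:
                f_map[i, j] = res.f_iccs
                d_map[i, j] = res.distance_nm
                valid[i, j] = True

    return ColocalizationMap(
        f_map=f_map, d_map=d_map, valid=valid, window=window, step=step,
        center_rows=row_starts + window // 2, center_cols=col_starts + window // 2,
        pixel_size=img_1.pixel_size)


def radial_profile(surface: CorrelationSurface, n_bins: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal average of a correlation surface for 1D plotting.

    Returns (radius_nm, mean G) with one bin per integer pixel radius by
    default.
    """
    xi, eta = surface.lag_grids()
    r = np.hypot(xi, eta).ravel()
    v = surface.values.ravel()
    ok = np.isfinite(v)
    r, v = r[ok], v[ok]
    if n_bins is None:
        n_bins = surface.max_lag + 1
    edges = np.linspace(0, surface.max_lag + 0.5, n_bins + 1)
    idx = np.digitize(r, edges) - 1
    radius, mean = [], []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            radius.append(r[m].mean() * surface.pixel_size)
            mean.append(v[m].mean())
    return np.asarray(radius), np.asarray(mean)


def predicted_distance_estimate(pair_distance: float, psf_width: float,
                                loc_precision: float = 0.0,
                                pixel_size: float = 10.0,
                                max_lag: int = DEFAULT_MAX_LAG,
                                fit_radius: int | None = None) -> float:
    """Model prediction of the recovered distance for a planted separation.

    For particle pairs at fixed distance ``d0`` with uniform random
    orientation, the noiseless cross-correlation is the PSF autocorrelation
    convolved with a ring of radius d0: radially,

        G(r) proportional to exp(-(r - d0)^2 / (2 s^2)) * i0e(r d0 / s^2),

    with per-axis variance s^2 = 2*psf_width^2 + 2*loc_precision^2 (each of
    the two partner localizations carries independent position noise, which
    broadens the pair-separation distribution but not the autocorrelation,
    whose per-axis variance stays 2*psf_width^2). The model surfaces are
    evaluated on the lag grid, fitted with the same Gaussian model as the
    measurements, and pushed through the same broadening quadrature. The
    returned value is the estimator's expectation, including its bias at
    distances below the rendering width.
    """
    s2 = 2.0 * psf_width**2 + 2.0 * loc_precision**2
    s2_auto = 2.0 * psf_width**2
    lag = np.arange(-max_lag, max_lag + 1) * pixel_size
    xi, eta = np.meshgrid(lag, lag)
    r = np.hypot(xi, eta)
    cross_vals = np.exp(-(r - pair_distance)**2 / (2 * s2)) * i0e(r * pair_distance / s2)
    auto_vals = np.exp(-r**2 / (2 * s2_auto))

    counts = np.ones(cross_vals.shape, dtype=int)
    cross = CorrelationSurface(cross_vals, pixel_size, "cross", counts)
    auto = CorrelationSurface(auto_vals, pixel_size, "auto", counts)
    fc = fit_correlation(cross, fit_radius=fit_radius)
    fa = fit_correlation(auto, fit_radius=fit_radius)
    d, _ = _distance_from_widths(fc.width_nm, fa.width_nm, fa.width_nm)
    return d
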