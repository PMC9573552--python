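"""Spot centroid extraction.

Two extractors:

* the classical per-sub-aperture center of gravity — an intensity-weighted
  mean restricted to each lenslet's detector window, with the classical
  failure mode built in (a window that receives essentially no light
  reports its own center, i.e. zero displacement);
* the whole-frame matched-filter (autocorrelation) method — the frame is
  correlated with a Gaussian template in the frequency domain, the k
  strongest response peaks are taken iteratively with local suppression,
  and each peak is refined to sub-pixel accuracy by a Gaussian-weighted
  centroid of the bilinearly subsampled response.

The whole-frame method is not restricted to sub-aperture windows, which is
what extends the sensor's dynamic range once spots wander out of their own
lenslet's window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import fftconvolve
from scipy.special import erf

from .forward_model import LensletGeometry, SpotFrame

__all__ = [
    "CorrelatorTemplate",
    "ResponseMap",
    "CentroidSet",
    "gaussian_template",
    "cog_subaperture",
    "cog_all",
    "correlate",
    "refine_subpixel",
    "extract_centroids",
]

#: fraction of the frame maximum below which a window is declared dark
LOW_FLUX_FRACTION = 1e-6


@dataclass
class CorrelatorTemplate:
    """Matched-filter template H: a small non-negative profile whose peak
    sits at ``center_offset`` (template pixel coordinates)."""

    profile: np.ndarray
    center_offset: tuple[float, float]
    sigma_px: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.profile, dtype=float)
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("template must be finite and non-negative")
        self.profile = p


@dataclass
class ResponseMap:
    """Matched-filter response CR on the frame pixel grid."""

    values: np.ndarray


@dataclass
class CentroidSet:
    """Unordered spot positions (x, y) in global frame pixels."""

    points: np.ndarray  # (k, 2)
    source: str = "autocorrelation"  # "classical" | "autocorrelation"
    peak_response: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    def __len__(self) -> int:
        return int(self.points.shape[0])


def gaussian_template(sigma_px: float = 1.0, radius: int | None = None) -> CorrelatorTemplate:
    """Pixel-integrated circular Gaussian template of width ``sigma_px``.

    ``radius`` defaults to ceil(4 sigma); the template side is 2*radius+1
    (odd), peak at the central pixel.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    r = int(np.ceil(4.0 * sigma_px)) if radius is None else int(radius)
    coords = np.arange(-r, r + 1, dtype=float)
    s = sigma_px * np.sqrt(2.0)
    one_d = 0.5 * (erf((coords + 0.5) / s) - erf((coords - 0.5) / s))
    prof = np.outer(one_d, one_d)
    return CorrelatorTemplate(profile=prof, center_offset=(r, r), sigma_px=sigma_px)


# ---------------------------------------------------------------------------
# Classical per-window center of gravity


def cog_subaperture(
    frame: SpotFrame,
    lenslet: int,
    geometry: LensletGeometry | None = None,
    flux_fraction: float = LOW_FLUX_FRACTION,
) -> tuple[float, float]:
    """Center of gravity of one lenslet's detector window, global pixels.

    The weighted mean runs over the window only.  If the window's total
    intensity falls below ``flux_fraction`` times the frame maximum the
    spot has left the window and the window center (the lenslet's reference
    position, i.e. zero measured displacement) is returned — the classical
    algorithm's failure mode.
    """
    geometry = geometry or frame.geometry
    rs, cs = geometry.window(lenslet)
    win = frame.intensity[rs, cs]
    total = win.sum()
    if total <= flux_fraction * frame.intensity.max():
        cx, cy = geometry.window_center(lenslet)
        return float(cx), float(cy)
    ys = np.arange(rs.start, rs.stop, dtype=float)
    xs = np.arange(cs.start, cs.stop, dtype=float)
    x = float((win.sum(axis=0) * xs).sum() / total)
    y = float((win.sum(axis=1) * ys).sum() / total)
    return x, y


def cog_all(frame: SpotFrame, geometry: LensletGeometry | None = None) -> CentroidSet:
    """Classical centroids for every effective lenslet, in lenslet order
    (the ordering is itself the classical identity assignment)."""
    geometry = geometry or frame.geometry
    pts = np.array(
        [cog_subaperture(frame, i, geometry) for i in range(geometry.k_effective)]
    )
    return CentroidSet(points=pts, source="classical")


# ---------------------------------------------------------------------------
# Whole-frame matched filter


def correlate(frame: SpotFrame | np.ndarray, template: CorrelatorTemplate) -> ResponseMap:
    """Matched-filter response of the frame to the template.

    Computed as a frequency-domain product (FFT convolution with the
    spatially reversed template, i.e. cross-correlation), zero-padded to a
    linear — not circular — correlation and cropped to the frame grid, so
    the response of an isolated spot peaks at the spot center.  For the
    symmetric Gaussian template, correlation and the convolution form are
    identical.
    """
    image = frame.intensity if isinstance(frame, SpotFrame) else np.asarray(frame, float)
    h = template.profile
    if h.shape[0] > image.shape[0] or h.shape[1] > image.shape[1]:
        raise ValueError("template must be smaller than the frame")
    return ResponseMap(values=fftconvolve(image, h[::-1, ::-1], mode="same"))


def refine_subpixel(
    response: ResponseMap | np.ndarray,
    peak: tuple[int, int],
    half_width: int = 3,
    subsample: int = 10,
    weight_sigma: float = 1.0,
    max_iter: int = 40,
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Sub-pixel peak position by Gaussian-weighted bilinear interpolation.

    The response is bilinearly subsampled on a ``(2*half_width)`` px window
    around the integer peak (``subsample`` sub-pixels per pixel, window
    clamped at the frame border) and the position is the Gaussian-weighted
    intensity centroid of the sub-samples.  The Gaussian weight is
    re-centered on the running estimate and iterated to its fixed point,
    which removes the pull toward the integer pixel that a single weighted
    pass suffers.

    Degenerate (flat or non-positive) windows return the integer peak.
    """
    r = response.values if isinstance(response, ResponseMap) else np.asarray(response)
    out = _refine_batch(
        r, np.array([peak], dtype=float), half_width, subsample, weight_sigma,
        max_iter, tol,
    )[0]
    return float(out[0]), float(out[1])


def _refine_batch(
    r: np.ndarray,
    peaks_xy: np.ndarray,
    half_width: int,
    subsample: int,
    weight_sigma: float,
    max_iter: int = 60,
    tol: float = 5e-5,
) -> np.ndarray:
    """Vectorized fixed-point refinement of many peaks at once: the
    subsample window and the Gaussian weight are both re-centered on each
    running estimate every iteration."""
    h, w = r.shape
    offs = np.linspace(-half_width, half_width, 2 * half_width * subsample + 1)
    ox, oy = np.meshgrid(offs, offs)  # (s, s)
    centers = peaks_xy.astype(float).copy()  # (k, 2)
    start = peaks_xy.astype(float).copy()
    inv2s2 = 1.0 / (2.0 * weight_sigma**2)
    for _ in range(max_iter):
        gx = np.clip(centers[:, 0, None, None] + ox, 0, w - 1)  # (k, s, s)
        gy = np.clip(centers[:, 1, None, None] + oy, 0, h - 1)
        vals = map_coordinates(r, [gy.ravel(), gx.ravel()], order=1).reshape(gx.shape)
        vals = np.maximum(vals, 0.0)
        wgt = np.exp(
            -(
                (gx - centers[:, 0, None, None]) ** 2
                + (gy - centers[:, 1, None, None]) ** 2
            )
            * inv2s2
        )
        m = wgt * vals
        tot = m.sum(axis=(1, 2))
        dead = tot <= 0
        tot = np.where(dead, 1.0, tot)
        nx = (m * gx).sum(axis=(1, 2)) / tot
        ny = (m * gy).sum(axis=(1, 2)) / tot
        new = np.column_stack([nx, ny])
        new[dead] = start[dead]
        shift = np.abs(new - centers).max() if len(new) else 0.0
        centers = new
        if shift < tol:
            break
    return centers


def extract_centroids(
    frame: SpotFrame,
    template: CorrelatorTemplate,
    k: int | None = None,
    suppression_radius: int | None = None,
    half_width: int = 3,
    subsample: int = 10,
    response: ResponseMap | None = None,
) -> CentroidSet:
    """Whole-frame iterative peak extraction: the k strongest matched-filter
    responses anywhere on the frame, each refined to sub-pixel accuracy.

    At each step the global response maximum is located (ties resolved in
    row-major scan order by ``argmax``), refined on the *unsuppressed*
    response, and a disk of ``suppression_radius`` pixels (default
    ceil(3 sigma)) around the integer peak is zeroed before the next
    search.  Raises if the response is exhausted before k peaks are found.
    """
    geometry = frame.geometry
    if k is None:
        k = geometry.k_effective
    if k < 1:
        raise ValueError("k must be >= 1")
    sigma = template.sigma_px or 1.0
    if suppression_radius is None:
        suppression_radius = int(np.ceil(3.0 * sigma))
    resp = correlate(frame, template) if response is None else response
    work = resp.values.copy()
    h, w = work.shape
    sr = int(suppression_radius)
    dyy, dxx = np.mgrid[-sr : sr + 1, -sr : sr + 1]
    disk = dyy**2 + dxx**2 <= sr**2
    int_peaks = np.empty((k, 2), dtype=int)
    peaks = np.empty(k)
    for i in range(k):
        flat = int(np.argmax(work))
        iy, ix = divmod(flat, w)
        if work[iy, ix] <= 0:
            raise RuntimeError(
                f"response exhausted after {i} of {k} requested centroids"
            )
        peaks[i] = work[iy, ix]
        int_peaks[i] = (ix, iy)
        y0, y1 = max(iy - sr, 0), min(iy + sr + 1, h)
        x0, x1 = max(ix - sr, 0), min(ix + sr + 1, w)
        work[y0:y1, x0:x1][disk[y0 - iy + sr : y1 - iy + sr, x0 - ix + sr : x1 - ix + sr]] = 0.0
    pts = _refine_batch(
        resp.values, int_peaks.astype(float), half_width, subsample, sigma
    )
    return CentroidSet(points=pts, source="autocorrelation", peak_response=peaks)
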