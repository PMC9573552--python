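"""Modal wavefront reconstruction from matched centroids.

Slopes: for lenslet i with assigned centroid (x_i, y_i) and calibrated
reference (x_0, y_0), the mean sub-aperture slope is
``g_x(i) = (x_i - x_0) * pixel / f`` (radians), likewise in y.

Modal solve: the slope vector G (interleaved Gx, Gy per lenslet) relates to
the Zernike coefficient vector A through the mode-coefficient matrix D of
sub-aperture-averaged mode gradients, G = D A + eps; the least-squares
solution A = D+ G uses the SVD pseudo-inverse with a relative
singular-value cutoff.  Piston and the two tilts are excluded from the
solved mode set; residual global tilt is reported as the mean residual
slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .centroid import CentroidSet
from .forward_model import LensletGeometry, subaperture_gradient_matrix
from .matcher import SpotAssignment
from .zernike import (
    ZernikeCoefficients,
    ZernikeIndex,
    synthesize,
)

__all__ = [
    "SlopeVector",
    "ReconOperator",
    "ReconResult",
    "slopes_from_centroids",
    "build_recon_operator",
    "solve_coefficients",
    "reconstruction_error",
    "reconstruct",
]

#: relative singular-value cutoff for the pseudo-inverse
SVD_CUTOFF = 1e-6


@dataclass
class SlopeVector:
    """Length-2m slope vector ordered (Gx(0), Gy(0), ..., Gx(m-1), Gy(m-1)),
    radians."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("slopes must be finite")


@dataclass
class ReconOperator:
    """Mode-coefficient matrix D (2m x n, radians of slope per wave of
    coefficient) and its SVD pseudo-inverse."""

    D: np.ndarray
    D_pinv: np.ndarray
    modes: list[ZernikeIndex]
    n_modes_full: int
    cutoff: float = SVD_CUTOFF
    condition_number: float = field(default=np.nan)


@dataclass
class ReconResult:
    """Solved coefficients plus residual and error metrics."""

    coefficients: ZernikeCoefficients
    residual_slope_rms: float
    mean_residual_slope: tuple[float, float]
    rms_error_waves: float | None = None
    rms_error_relative: float | None = None


def slopes_from_centroids(
    centroids: CentroidSet,
    assignment: SpotAssignment | None,
    geometry: LensletGeometry,
) -> SlopeVector:
    """Per-lenslet slopes from an assigned centroid set.

    ``assignment=None`` means identity order (centroid i belongs to
    lenslet i) — the classical-pipeline adapter for window-CoG centroids,
    which are produced in lenslet order.
    """
    k = geometry.k_effective
    if len(centroids) != k:
        raise ValueError(f"expected {k} centroids, got {len(centroids)}")
    if assignment is None:
        per_lenslet = centroids.points
    else:
        if assignment.mapping.size != k or np.any(assignment.mapping < 0):
            raise ValueError("assignment must be a complete bijection")
        per_lenslet = centroids.points[assignment.inverse()]
    disp_px = per_lenslet - geometry.reference_centers
    slopes = disp_px * geometry.config.pixel_size_um / geometry.config.focal_length_um
    return SlopeVector(values=slopes.reshape(-1))


def build_recon_operator(
    geometry: LensletGeometry,
    modes: list[ZernikeIndex],
    n_modes_full: int | None = None,
    cutoff: float = SVD_CUTOFF,
) -> ReconOperator:
    """Assemble D from sub-aperture-averaged analytic mode gradients (the
    same quadrature as the forward model) and its pseudo-inverse."""
    if not modes:
        raise ValueError("need at least one mode")
    if 2 * geometry.k_effective < len(modes):
        raise ValueError("under-determined: fewer slope measurements than modes")
    D = subaperture_gradient_matrix(geometry, modes) * geometry.slope_per_unit_gradient
    s = np.linalg.svd(D, compute_uv=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else np.inf
    if s[-1] < cutoff * s[0]:
        warnings.warn(
            f"reconstruction operator is rank deficient beyond the cutoff "
            f"(condition number {cond:.3g}); small singular values discarded"
        )
    D_pinv = np.linalg.pinv(D, rcond=cutoff)
    if n_modes_full is None:
        n_modes_full = max(z.j for z in modes) + 1
    return ReconOperator(
        D=D, D_pinv=D_pinv, modes=list(modes), n_modes_full=n_modes_full,
        cutoff=cutoff, condition_number=cond,
    )


def solve_coefficients(G: SlopeVector, op: ReconOperator) -> ZernikeCoefficients:
    """Least-squares modal coefficients A = D+ G, embedded in a full-length
    OSA vector (excluded modes stay zero)."""
    g = G.values
    if g.size != op.D.shape[0]:
        raise ValueError(
            f"slope vector length {g.size} does not match operator ({op.D.shape[0]})"
        )
    a = op.D_pinv @ g
    return ZernikeCoefficients.from_subset(op.modes, a, op.n_modes_full)


def reconstruct(
    centroids: CentroidSet,
    assignment: SpotAssignment | None,
    geometry: LensletGeometry,
    op: ReconOperator,
    reference: ZernikeCoefficients | None = None,
    grid: int = 256,
) -> ReconResult:
    """Full solve from a matched centroid set, with error metrics against a
    reference wavefront when one is given."""
    G = slopes_from_centroids(centroids, assignment, geometry)
    coeffs = solve_coefficients(G, op)
    residual = G.values - op.D @ coeffs.subset(op.modes)
    res = ReconResult(
        coefficients=coeffs,
        residual_slope_rms=float(np.sqrt(np.mean(residual**2))),
        mean_residual_slope=(float(residual[0::2].mean()), float(residual[1::2].mean())),
    )
    if reference is not None:
        res.rms_error_waves, res.rms_error_relative = reconstruction_error(
            coeffs, reference, grid=grid
        )
    return res


def reconstruction_error(
    result: ZernikeCoefficients,
    reference: ZernikeCoefficients,
    grid: int = 256,
) -> tuple[float, float | None]:
    """RMS of the pointwise difference of the synthesized wavefront maps
    over the pupil (waves), and the same divided by the reference RMS.

    A zero-RMS reference makes the relative error undefined (None).
    """
    n = max(result.n_modes, reference.n_modes)
    a = np.zeros(n)
    a[: result.n_modes] = result.values
    b = np.zeros(n)
    b[: reference.n_modes] = reference.values
    diff = ZernikeCoefficients(values=a - b, excludes_piston_tilt=False)
    rms_abs = synthesize(diff, grid=grid).rms()
    ref_rms = synthesize(
        ZernikeCoefficients(values=b, excludes_piston_tilt=False), grid=grid
    ).rms()
    if ref_rms == 0.0:
        warnings.warn("relative reconstruction error undefined for zero reference")
        return rms_abs, None
    return rms_abs, rms_abs / ref_rms
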