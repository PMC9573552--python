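"""Zernike polynomials on the unit disk: evaluation, analytic gradients,
mode bookkeeping, and random coefficient sampling.

Conventions
-----------
* OSA/ANSI single index ``j`` with double-index labels ``(n, m)``;
  ``j = (n(n+2) + m) / 2``.  Negative ``m`` selects the ``sin`` harmonic.
* Unit-RMS (Noll-style) normalization: each mode has RMS 1 over the unit
  disk, so a coefficient equals that mode's RMS contribution to the
  wavefront and, for piston-free vectors, the wavefront RMS equals the
  Euclidean norm of the coefficient vector.
* Coefficients are in waves (wavelength-normalized optical path) unless a
  caller re-interprets them; all geometry conversions happen downstream.

Every mode is expanded once into an exact Cartesian monomial table
``{(px, py): c}``; evaluation and differentiation are then termwise, so
analytic gradients carry no quadrature or recurrence error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "ZernikeIndex",
    "ZernikeCoefficients",
    "WavefrontMap",
    "osa_index",
    "index_from_osa",
    "mode_list",
    "evaluate_mode",
    "evaluate_mode_xy",
    "evaluate_gradient",
    "basis_matrix",
    "gradient_matrices",
    "sample_coefficients",
    "synthesize",
    "pupil_grid",
]


@dataclass(frozen=True)
class ZernikeIndex:
    """One Zernike mode: radial order ``n``, azimuthal frequency ``m``,
    OSA/ANSI position ``j``."""

    j: int
    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n < 0 or abs(self.m) > self.n or (self.n - abs(self.m)) % 2:
            raise ValueError(f"invalid Zernike index (n={self.n}, m={self.m})")
        if osa_index(self.n, self.m) != self.j:
            raise ValueError(
                f"j={self.j} inconsistent with (n={self.n}, m={self.m})"
            )

    def label(self) -> str:
        return f"Z{self.n}^{self.m}"


def osa_index(n: int, m: int) -> int:
    """OSA/ANSI single index for the mode (n, m)."""
    return (n * (n + 2) + m) // 2


def index_from_osa(j: int) -> ZernikeIndex:
    """Invert the OSA single index."""
    if j < 0:
        raise ValueError("j must be >= 0")
    n = int(math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    return ZernikeIndex(j=j, n=n, m=m)


#: OSA positions of piston and the two tilts.
PISTON_TILT_J = (0, 1, 2)


def mode_list(n_modes: int, exclude_piston_tilt: bool = True) -> list[ZernikeIndex]:
    """Canonical mode list: the first ``n_modes`` OSA modes, optionally with
    piston (j=0) and the two tilts (j=1,2) removed.

    The removed modes keep their ``j`` positions in any full-length
    coefficient vector; they are simply absent from the reconstructed set.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    modes = [index_from_osa(j) for j in range(n_modes)]
    if exclude_piston_tilt:
        modes = [z for z in modes if z.j not in PISTON_TILT_J]
    return modes


# ---------------------------------------------------------------------------
# Monomial expansion


@lru_cache(maxsize=None)
def _monomials(n: int, m: int) -> tuple[tuple[int, int, float], ...]:
    """Exact Cartesian monomial expansion of the unit-RMS mode (n, m):
    a tuple of (px, py, coeff) with Z = sum c * x**px * y**py."""
    am = abs(m)
    norm = math.sqrt(2.0 * (n + 1) / (1.0 + (m == 0)))
    acc: dict[tuple[int, int], float] = {}
    for s in range((n - am) // 2 + 1):
        rad = (
            (-1.0) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + am) // 2 - s)
                * math.factorial((n - am) // 2 - s)
            )
        )
        q = (n - 2 * s - am) // 2  # power of (x^2 + y^2)
        # rho^am * cos/sin(am * theta) from (x + i y)^am
        for k in range(am + 1):
            if m >= 0 and k % 2 == 0:
                trig = (-1.0) ** (k // 2)
            elif m < 0 and k % 2 == 1:
                trig = (-1.0) ** ((k - 1) // 2)
            else:
                continue
            c0 = rad * math.comb(am, k) * trig
            # multiply by (x^2+y^2)^q
            for t in range(q + 1):
                c = c0 * math.comb(q, t)
                key = (am - k + 2 * (q - t), k + 2 * t)
                acc[key] = acc.get(key, 0.0) + c
    return tuple(
        (px, py, norm * c) for (px, py), c in sorted(acc.items()) if c != 0.0
    )


def evaluate_mode_xy(idx: ZernikeIndex, x, y):
    """Unit-RMS mode value at Cartesian pupil coordinates (vectorized)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.zeros(np.broadcast(x, y).shape)
    for px, py, c in _monomials(idx.n, idx.m):
        out += c * x**px * y**py
    return out


def evaluate_mode(idx: ZernikeIndex, rho, theta, strict: bool = True):
    """Unit-RMS mode value at polar pupil coordinates ``(rho, theta)``.

    With ``strict`` (default) any ``rho > 1`` raises; otherwise those points
    are evaluated by analytic continuation of the polynomial.
    """
    rho = np.asarray(rho, dtype=float)
    if strict and np.any(rho > 1.0 + 1e-12):
        raise ValueError("rho > 1 is outside the pupil")
    if np.any(rho < 0):
        raise ValueError("rho must be >= 0")
    return evaluate_mode_xy(idx, rho * np.cos(theta), rho * np.sin(theta))


def evaluate_gradient(idx: ZernikeIndex, x, y, strict: bool = True):
    """Analytic Cartesian gradient (dZ/dx, dZ/dy) of the unit-RMS mode."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if strict and np.any(x**2 + y**2 > 1.0 + 1e-12):
        raise ValueError("point outside the unit pupil")
    gx = np.zeros(np.broadcast(x, y).shape)
    gy = np.zeros_like(gx)
    for px, py, c in _monomials(idx.n, idx.m):
        if px > 0:
            gx += c * px * x ** (px - 1) * y**py
        if py > 0:
            gy += c * py * x**px * y ** (py - 1)
    return gx, gy


def basis_matrix(modes: list[ZernikeIndex], x, y) -> np.ndarray:
    """Stack mode values at the given points: shape (npoints, nmodes)."""
    x = np.ravel(np.asarray(x, dtype=float))
    y = np.ravel(np.asarray(y, dtype=float))
    return np.column_stack([evaluate_mode_xy(z, x, y) for z in modes])


def gradient_matrices(modes: list[ZernikeIndex], x, y):
    """Stacked analytic gradients: two (npoints, nmodes) arrays (d/dx, d/dy)."""
    x = np.ravel(np.asarray(x, dtype=float))
    y = np.ravel(np.asarray(y, dtype=float))
    gxs, gys = [], []
    for z in modes:
        gx, gy = evaluate_gradient(z, x, y, strict=False)
        gxs.append(gx)
        gys.append(gy)
    return np.column_stack(gxs), np.column_stack(gys)


# ---------------------------------------------------------------------------
# Coefficient vectors and wavefront maps


@dataclass
class ZernikeCoefficients:
    """Full-length OSA-ordered coefficient vector, in waves.

    ``values[j]`` is the coefficient of OSA mode ``j``; excluded modes
    (piston/tilt) are stored as zeros so vectors of equal ``n_modes`` are
    directly comparable.
    """

    values: np.ndarray
    excludes_piston_tilt: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.ndim != 1:
            raise ValueError("coefficient vector must be 1-D")
        if self.excludes_piston_tilt:
            for j in PISTON_TILT_J:
                if j < self.values.size and self.values[j] != 0.0:
                    raise ValueError(
                        "piston/tilt coefficients must be zero when excluded"
                    )

    @property
    def n_modes(self) -> int:
        return int(self.values.size)

    def rms(self) -> float:
        """Wavefront RMS implied by the coefficients (piston ignored)."""
        v = self.values.copy()
        if v.size:
            v[0] = 0.0
        return float(np.linalg.norm(v))

    def subset(self, modes: list[ZernikeIndex]) -> np.ndarray:
        return self.values[[z.j for z in modes]]

    @classmethod
    def from_subset(
        cls, modes: list[ZernikeIndex], sub_values, n_modes: int
    ) -> "ZernikeCoefficients":
        full = np.zeros(n_modes)
        for z, v in zip(modes, np.asarray(sub_values, dtype=float)):
            full[z.j] = v
        return cls(values=full)

    @classmethod
    def single_mode(
        cls, mode: ZernikeIndex, amplitude: float, n_modes: int
    ) -> "ZernikeCoefficients":
        full = np.zeros(n_modes)
        full[mode.j] = amplitude
        return cls(values=full, excludes_piston_tilt=mode.j not in PISTON_TILT_J)

    def to_json(self) -> str:
        rows = []
        for j, v in enumerate(self.values):
            z = index_from_osa(j)
            rows.append({"j": j, "n": z.n, "m": z.m, "value": float(v)})
        return json.dumps(
            {
                "ordering": "OSA/ANSI",
                "normalization": "unit-RMS",
                "units": "waves",
                "excludes_piston_tilt": self.excludes_piston_tilt,
                "coefficients": rows,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ZernikeCoefficients":
        d = json.loads(text)
        rows = sorted(d["coefficients"], key=lambda r: r["j"])
        return cls(
            values=np.array([r["value"] for r in rows]),
            excludes_piston_tilt=bool(d.get("excludes_piston_tilt", True)),
        )


@dataclass
class WavefrontMap:
    """Phase samples (waves) over a square grid covering the unit pupil."""

    phase: np.ndarray
    mask: np.ndarray
    grid: int = 256

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.phase[self.mask] ** 2)))


@lru_cache(maxsize=8)
def pupil_grid(grid: int = 256):
    """Pixel-center sample coordinates of a ``grid`` x ``grid`` unit-disk
    raster: returns (x, y, mask) with x, y in [-1, 1]."""
    c = (np.arange(grid) + 0.5) / grid * 2.0 - 1.0
    x, y = np.meshgrid(c, c)
    mask = x**2 + y**2 <= 1.0
    return x, y, mask


@lru_cache(maxsize=32)
def _cached_basis(n_modes: int, grid: int) -> np.ndarray:
    x, y, mask = pupil_grid(grid)
    modes = [index_from_osa(j) for j in range(n_modes)]
    return basis_matrix(modes, x[mask], y[mask])


def synthesize(coeffs: ZernikeCoefficients, grid: int = 256) -> WavefrontMap:
    """Pixelwise modal sum phi = sum_k a_k Z_k over the pupil raster."""
    x, y, mask = pupil_grid(grid)
    basis = _cached_basis(coeffs.n_modes, grid)
    phase = np.zeros((grid, grid))
    phase[mask] = basis @ coeffs.values
    return WavefrontMap(phase=phase, mask=mask, grid=grid)


# ---------------------------------------------------------------------------
# Random wavefronts

#: Kolmogorov-like radial-order decay exponent for coefficient std dev.
KL_DECAY_EXPONENT = -11.0 / 6.0


def sample_coefficients(
    rng: np.random.Generator | int,
    n_modes: int = 15,
    target_rms: float | None = None,
    rms_range: tuple[float, float] = (0.1, 2.0),
    decay_exponent: float = KL_DECAY_EXPONENT,
) -> ZernikeCoefficients:
    """Random turbulence-weighted coefficients.

    Coefficients are independent zero-mean Gaussians with standard deviation
    proportional to ``(n_radial + 1) ** decay_exponent`` (a Karhunen-Loeve /
    Kolmogorov-like spectrum: low orders dominate), piston and tilt forced
    to zero, then rescaled so the wavefront RMS equals ``target_rms``
    (or a uniform draw from ``rms_range`` when ``target_rms`` is None).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if target_rms is None:
        lo, hi = rms_range
        target_rms = float(rng.uniform(lo, hi))
    if target_rms < 0:
        raise ValueError("target_rms must be >= 0")
    sigma = np.array(
        [(index_from_osa(j).n + 1.0) ** decay_exponent for j in range(n_modes)]
    )
    values = rng.standard_normal(n_modes) * sigma
    for j in PISTON_TILT_J:
        if j < n_modes:
            values[j] = 0.0
    norm = np.linalg.norm(values)
    values = values * (target_rms / norm) if norm > 0 else values * 0.0
    return ZernikeCoefficients(values=values)
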