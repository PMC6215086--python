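"""Autofocus search, water/tissue interface detection, and focal-plane
curvature characterization by Zernike decomposition.

The autofocus metric is deliberately cheap — the mean intensity of the
central A-line — and is maximized with the classical Fibonacci elimination
scheme for a unimodal function, which guarantees a final bracket of
``(b - a) / F(n + 1)`` after ``n`` metric evaluations.

The interface detector convolves the axial intensity profile with the
first derivative of a Gaussian and takes the depth of the maximum rising
(dark water above, bright tissue below) response.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from ._exceptions import NoInterfaceError
from .recon import IntensityVolume

__all__ = [
    "FocusResult",
    "InterfaceSurface",
    "ZernikeCoeffs",
    "focus_metric",
    "fibonacci_search",
    "detect_interface_depth",
    "interface_surface",
    "zernike_basis",
    "zernike_decompose",
    "zernike_reconstruct",
]


@dataclass
class FocusResult:
    best_z_um: float
    n_evaluations: int
    bracket_um: tuple[float, float]
    trace: list[tuple[float, float]]  # (z, metric) in evaluation order


@dataclass
class InterfaceSurface:
    """Per-(x, y) water/tissue interface depth map with a validity mask."""

    depth_um: np.ndarray
    valid: np.ndarray
    pixel_um: float = 1.0


@dataclass
class ZernikeCoeffs:
    """Least-squares coefficients c_j of the single-index ANSI polynomials
    Z0..Z5 (piston, tip, tilt, oblique astigmatism, defocus, vertical
    astigmatism) on the unit disk, plus their normalized |c_j| amplitudes."""

    coeffs: np.ndarray
    normalized_amplitudes: np.ndarray
    residual_rms: float
    center_um: tuple[float, float] = (0.0, 0.0)
    radius_um: float = 1.0


def focus_metric(vol: IntensityVolume) -> float:
    """Average intensity within the A-line at the center of the lateral FOV."""
    inten = vol.intensity
    if inten.size == 0:
        raise ValueError("empty volume")
    return float(inten[:, inten.shape[1] // 2, inten.shape[2] // 2].mean())


@lru_cache(maxsize=None)
def _fibonacci(n: int) -> int:
    """F(1) = F(2) = 1 Fibonacci numbers, integer-exact."""
    if n < 1:
        raise ValueError("Fibonacci index must be >= 1")
    a, b = 1, 1
    for _ in range(n - 2):
        a, b = b, a + b
    return b if n > 1 else 1


def fibonacci_search(
    evaluate, bracket: tuple[float, float], n_evals: int
) -> FocusResult:
    """Maximize a unimodal function on ``bracket`` with ``n_evals``
    evaluations using Fibonacci-ratio interval elimination.

    Final bracket length is ``(b - a) / F(n_evals + 1)`` (the degenerate
    last comparison is resolved with a relative perturbation of 1e-9 of the
    current interval, which is absorbed into the reported bracket).
    Raises on a non-finite metric value.
    """
    a, b = float(bracket[0]), float(bracket[1])
    if not a < b:
        raise ValueError("bracket must satisfy a < b")
    n = int(n_evals)
    if n < 2:
        raise ValueError("n_evals must be >= 2")
    trace: list[tuple[float, float]] = []

    def f(z: float) -> float:
        val = float(evaluate(z))
        if not np.isfinite(val):
            raise RuntimeError("non-finite focus metric at z = %g" % z)
        trace.append((z, val))
        return val

    length = b - a
    x1 = a + length * _fibonacci(n - 1) / _fibonacci(n + 1)
    x2 = a + length * _fibonacci(n) / _fibonacci(n + 1)
    f1, f2 = f(x1), f(x2)
    for k in range(1, n - 1):
        if f1 > f2:  # maximum lies in [a, x2]
            b, x2, f2 = x2, x1, f1
            x1 = a + (b - a) * _fibonacci(n - k - 1) / _fibonacci(n - k + 1)
            if np.isclose(x1, x2, rtol=0, atol=1e-9 * (b - a) + 1e-300):
                x1 = x2 - 1e-9 * (b - a)
            f1 = f(x1)
        else:  # maximum lies in [x1, b]
            a, x1, f1 = x1, x2, f2
            x2 = a + (b - a) * _fibonacci(n - k) / _fibonacci(n - k + 1)
            if np.isclose(x2, x1, rtol=0, atol=1e-9 * (b - a) + 1e-300):
                x2 = x1 + 1e-9 * (b - a)
            f2 = f(x2)
    if f1 > f2:
        b = x2
    else:
        a = x1
    return FocusResult(
        best_z_um=0.5 * (a + b),
        n_evaluations=len(trace),
        bracket_um=(a, b),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Interface detection
# ---------------------------------------------------------------------------

def detect_interface_depth(
    profile: np.ndarray,
    z_step_um: float = 50.0,
    sigma_um: float = 50.0,
    min_response: float = 0.3,
) -> float:
    """Depth of the water/tissue interface along one axial profile.

    Convolves the profile with the first derivative of a Gaussian
    (sigma = ``sigma_um``) and returns the depth of the maximum *rising*
    (dark-to-bright) response.  The response is normalized so a clean unit
    step scores 1; profiles whose best rising response falls below
    ``min_response`` (flat profiles, falling edges) raise NoInterfaceError.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 5:
        raise ValueError("profile must be 1-D with >= 5 samples")
    span = float(np.ptp(p))
    if span <= 0:
        raise NoInterfaceError("flat profile: no interface")
    sigma_samples = max(sigma_um / z_step_um, 0.3)
    response = ndimage.gaussian_filter1d(p, sigma=sigma_samples, order=1, mode="nearest")
    # scale so a unit step yields a peak response of ~1
    norm = span / (sigma_samples * np.sqrt(2.0 * np.pi))
    scaled = response / norm
    idx = int(np.argmax(scaled))
    if scaled[idx] < min_response:
        raise NoInterfaceError("no rising edge above threshold")
    return idx * z_step_um


def interface_surface(
    vol: IntensityVolume, sigma_um: float = 50.0, min_response: float = 0.3
) -> InterfaceSurface:
    """Interface depth per lateral position (full axial sampling);
    positions without a detectable rising edge are masked out.

    Vectorized version of :func:`detect_interface_depth` applied to every
    A-line of the volume at once.
    """
    inten = vol.intensity
    if inten.ndim != 3 or inten.shape[0] < 5:
        raise ValueError("need a 3-D volume with >= 5 axial samples")
    dz = vol.voxel_size_um[0]
    sigma_samples = max(sigma_um / dz, 0.3)
    response = ndimage.gaussian_filter1d(
        inten, sigma=sigma_samples, axis=0, order=1, mode="nearest"
    )
    span = np.ptp(inten, axis=0)
    norm = span / (sigma_samples * np.sqrt(2.0 * np.pi))
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = response / np.where(norm > 0, norm, np.inf)
    idx = np.argmax(scaled, axis=0)
    peak = np.take_along_axis(scaled, idx[None], axis=0)[0]
    valid = (span > 0) & (peak >= min_response)
    depth = np.where(valid, idx * dz, np.nan)
    return InterfaceSurface(depth_um=depth, valid=valid, pixel_um=vol.voxel_size_um[1])


# ---------------------------------------------------------------------------
# Zernike decomposition
# ---------------------------------------------------------------------------

def zernike_basis(j: int, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Orthonormal single-index ANSI Zernike polynomial Z_j on the unit disk.

    j = 0..5: piston, tip (y), tilt (x), oblique astigmatism, defocus,
    vertical astigmatism.
    """
    rho2 = x**2 + y**2
    if j == 0:
        return np.ones_like(x)
    if j == 1:
        return 2.0 * y
    if j == 2:
        return 2.0 * x
    if j == 3:
        return np.sqrt(6.0) * 2.0 * x * y
    if j == 4:
        return np.sqrt(3.0) * (2.0 * rho2 - 1.0)
    if j == 5:
        return np.sqrt(6.0) * (x**2 - y**2)
    raise ValueError("only j <= 5 (low-order aberrations) are supported")


def zernike_decompose(
    surface: InterfaceSurface,
    center_um: tuple[float, float] | None = None,
    radius_um: float | None = None,
) -> ZernikeCoeffs:
    """Least-squares Zernike coefficients (j <= 5) of an interface depth map.

    Lateral coordinates are mapped onto the unit disk; by default the disk
    is centred on the valid-area centroid with the radius of the farthest
    valid point, but an explicit ``center_um`` / ``radius_um`` can pin the
    mapping (coefficients of non-piston terms depend on it).  Raises on
    rank deficiency (< 6 usable points or a degenerate point layout).
    """
    valid = surface.valid & np.isfinite(surface.depth_um)
    if valid.sum() < 6:
        raise ValueError("need >= 6 valid surface points")
    ii, jj = np.nonzero(valid)
    px = surface.pixel_um
    xs = ii * px
    ys = jj * px
    if center_um is None:
        cx, cy = xs.mean(), ys.mean()
    else:
        cx, cy = center_um
    if radius_um is None:
        radius = max(np.max(np.hypot(xs - cx, ys - cy)), 1e-12)
    else:
        radius = float(radius_um)
    x = (xs - cx) / radius
    y = (ys - cy) / radius
    design = np.column_stack([zernike_basis(j, x, y) for j in range(6)])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("rank-deficient Zernike design (degenerate layout)")
    heights = surface.depth_um[valid]
    coeffs, *_ = np.linalg.lstsq(design, heights, rcond=None)
    resid = heights - design @ coeffs
    total = np.abs(coeffs).sum()
    return ZernikeCoeffs(
        coeffs=coeffs,
        normalized_amplitudes=np.abs(coeffs) / (total if total > 0 else 1.0),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        center_um=(float(cx), float(cy)),
        radius_um=float(radius),
    )


def zernike_reconstruct(
    coeffs: np.ndarray, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Evaluate a Zernike expansion on unit-disk coordinates."""
    coeffs = np.asarray(coeffs, dtype=float)
    out = np.zeros_like(np.asarray(x, dtype=float))
    for j, c in enumerate(coeffs):
        out += c * zernike_basis(j, x, y)
    return out
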