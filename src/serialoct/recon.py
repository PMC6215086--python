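"""Fringe-to-intensity reconstruction, attenuation compensation, and
dynamic-focus (OCM) stack fusion.

The A-line chain is the standard swept-source recipe: subtract a reference
fringe (here the tile-average fringe), apply a Gaussian spectral apodization
window, inverse-transform, and keep the first half of the axial range
(Hermitian symmetry of a real-valued signal).  Intensity is the squared
modulus, scaled so that an on-bin reflector of amplitude ``a`` reconstructs
to intensity ``a**2``.

Attenuation follows a single-scattering model multiplied by the confocal
axial envelope:  I(z) = i0 * T(z) * exp(-2 mu (z - z_surface)).  The fit is
a weighted least squares on log-intensity (weights = intensity**2, the
Gaussian-noise linearization), solved in closed form per A-line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import DataError
from .optics import LaserSpec, TileSpec, confocal_factor

__all__ = [
    "TilePlacement",
    "FringeTile",
    "IntensityVolume",
    "AttenuationFit",
    "reconstruct_aline",
    "reconstruct_tile",
    "fit_attenuation",
    "pooled_attenuation_mm",
    "compensate_depth",
    "compensate_depth_resolved",
    "fuse_focal_stack",
    "fusion_weights",
]


@dataclass(frozen=True)
class TilePlacement:
    """Where one tile sits: stage-plane corner position of the tile footprint,
    depth of the current cut face in the sample frame, and the focus geometry
    along the A-line axis (depths measured from the zero-delay line).

    ``standoff_um`` is the water gap between the zero-delay line and the cut
    face; the tissue surface therefore sits at depth bin ``standoff / dz``.
    """

    x_um: float
    y_um: float
    slice_z_um: float = 0.0
    standoff_um: float = 100.0
    focal_plane_um: float | None = None  # default: focus at the cut face

    @property
    def focal_um(self) -> float:
        return self.standoff_um if self.focal_plane_um is None else self.focal_plane_um


@dataclass
class FringeTile:
    """Raw k-linear interference fringes for one tile.

    fringes : (n_k, n_fast, n_slow) real array
    """

    fringes: np.ndarray
    k_grid: np.ndarray
    placement: TilePlacement
    laser: LaserSpec
    tile: TileSpec

    def __post_init__(self) -> None:
        self.fringes = np.asarray(self.fringes, dtype=float)
        self.k_grid = np.asarray(self.k_grid, dtype=float)
        if self.fringes.ndim != 3:
            raise ValueError("fringes must be (n_k, n_fast, n_slow)")
        dk = np.diff(self.k_grid)
        if not (dk > 0).all() or not np.allclose(dk, dk[0], rtol=1e-9):
            raise ValueError("k_grid must be strictly increasing and uniform")


@dataclass
class IntensityVolume:
    """Reconstructed OCT intensity, z (depth) x x (fast) x y (slow).

    ``cartesian_origin_um`` is the stage-plane position of the tile corner;
    ``surface_z_um`` the depth of the cut face along the A-line axis."""

    intensity: np.ndarray
    voxel_size_um: tuple[float, float, float]  # (dz, dx, dy)
    cartesian_origin_um: tuple[float, float] = (0.0, 0.0)
    focal_depth_um: float = 0.0
    surface_z_um: float = 0.0
    slice_z_um: float = 0.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be 3-D (z, x, y)")

    @property
    def depth_axis_um(self) -> np.ndarray:
        return np.arange(self.intensity.shape[0]) * self.voxel_size_um[0]


@dataclass
class AttenuationFit:
    """Per-A-line attenuation estimates for one tile.

    mu_mm : (n_fast, n_slow) attenuation coefficients, mm^-1 (>= 0)
    valid : mask of A-lines with enough signal for a fit
    """

    mu_mm: np.ndarray
    i0: np.ndarray
    valid: np.ndarray
    residual_rms: np.ndarray
    z_f_um: float
    z_r_um: float
    surface_z_um: float
    surface_map_um: np.ndarray | None = None  # per-A-line tissue onset
    mu_median_mm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.z_r_um <= 0:
            raise ValueError("z_r_um must be > 0")
        ok = self.valid & np.isfinite(self.mu_mm)
        self.mu_median_mm = float(np.median(self.mu_mm[ok])) if ok.any() else float("nan")


# ---------------------------------------------------------------------------
# A-line / tile reconstruction
# ---------------------------------------------------------------------------

def _reconstruct_spectra(signal: np.ndarray, laser: LaserSpec) -> np.ndarray:
    """Window + FFT + half-range + amplitude calibration for an array whose
    first axis is the k axis.  Returns intensity (amplitude squared)."""
    window = laser.apodization_window()
    shape = (-1,) + (1,) * (signal.ndim - 1)
    spectrum = np.fft.fft(signal * window.reshape(shape), axis=0)
    half = spectrum[: laser.n_k_samples // 2]
    amplitude = 2.0 * np.abs(half) / window.sum()
    return amplitude**2


def reconstruct_aline(
    fringe: np.ndarray, reference: np.ndarray, laser: LaserSpec
) -> np.ndarray:
    """Reconstruct one depth-intensity profile from one fringe.

    Returns a nonnegative profile of length ``laser.n_k_samples // 2``,
    sampled every ``laser.depth_bin_um()`` micrometres.
    """
    fringe = np.asarray(fringe, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fringe.shape != reference.shape or fringe.ndim != 1:
        raise ValueError("fringe and reference must be 1-D arrays of equal length")
    if fringe.shape[0] != laser.n_k_samples:
        raise ValueError("fringe length must equal laser.n_k_samples")
    return _reconstruct_spectra(fringe - reference, laser)


def reconstruct_tile(
    tile: FringeTile,
    reference: np.ndarray | None = None,
    reference_mode: str = "mean",
    reference_smooth_sigma: float = 32.0,
) -> IntensityVolume:
    """Reconstruct a whole tile.

    The reference fringe defaults to the average fringe over all lateral
    positions of the tile, which removes the common (reference-arm /
    source-envelope) background from every A-line.
    ``reference_mode="smoothed_mean"`` additionally low-passes the average
    fringe along k (Gaussian, ``reference_smooth_sigma`` samples): the
    background spectrum varies slowly in k while sample structure beyond a
    few tens of micrometres of depth oscillates fast, so smoothing keeps
    the background estimate but discards the residual average *signal*
    that plain mean subtraction would re-inject into every A-line.
    """
    if not np.isfinite(tile.fringes).all():
        raise DataError("tile contains non-finite fringe samples")
    if reference is None:
        reference = tile.fringes.mean(axis=(1, 2))
        if reference_mode == "smoothed_mean":
            from scipy import ndimage

            reference = ndimage.gaussian_filter1d(
                reference, sigma=reference_smooth_sigma, mode="nearest"
            )
        elif reference_mode != "mean":
            raise ValueError("reference_mode must be 'mean' or 'smoothed_mean'")
    intensity = _reconstruct_spectra(tile.fringes - reference[:, None, None], tile.laser)
    dz = tile.laser.depth_bin_um()
    px = tile.tile.pixel_um
    return IntensityVolume(
        intensity=intensity,
        voxel_size_um=(dz, px, px),
        cartesian_origin_um=(tile.placement.x_um, tile.placement.y_um),
        focal_depth_um=tile.placement.focal_um,
        surface_z_um=tile.placement.standoff_um,
        slice_z_um=tile.placement.slice_z_um,
    )


# ---------------------------------------------------------------------------
# Attenuation
# ---------------------------------------------------------------------------

def fit_attenuation(
    vol: IntensityVolume,
    tissue_surface_z_um: float | None = None,
    z_f_um: float | None = None,
    z_r_um: float | None = None,
    max_depth_um: float | None = None,
    min_samples: int = 16,
    floor_fraction: float = 1e-6,
    detect_surface: bool = False,
    onset_fraction: float = 0.2,
    onset_skip_um: float = 20.0,
    tissue_peak_fraction: float = 0.02,
    weighting: str = "intensity",
) -> AttenuationFit:
    """Fit I(z) = i0 * T(z) * exp(-2 mu (z - surface)) per A-line.

    Log-intensity weighted least squares over tissue voxels; bins below
    ``floor_fraction`` of the A-line maximum are excluded.
    ``weighting="intensity"`` uses weights I^2, the generalized
    least-squares choice when the dominant error is additive detector
    noise; ``weighting="uniform"`` is the GLS choice when the dominant
    deviation is multiplicative tissue texture (constant log-variance), as
    in structured parenchyma.

    With ``detect_surface=True`` each A-line's own tissue onset is located
    first (the first bin at or beyond the nominal surface whose intensity
    reaches ``onset_fraction`` of the A-line peak, plus ``onset_skip_um``
    to clear the edge-response ramp) and the decay is fitted from there, so
    A-lines entering the tissue through an agarose or water layer are
    handled correctly; A-lines whose peak stays below
    ``tissue_peak_fraction`` of the tile maximum carry no tissue and are
    flagged invalid.  Negative slopes are clipped to mu = 0.
    """
    surface = vol.surface_z_um if tissue_surface_z_um is None else tissue_surface_z_um
    z_f = vol.focal_depth_um if z_f_um is None else z_f_um
    z_r = 150.0 if z_r_um is None else z_r_um
    z = vol.depth_axis_um
    in_depth = z >= surface
    if int(in_depth.sum()) < min_samples:
        raise ValueError("need at least %d axial samples below the surface" % min_samples)

    intensity = vol.intensity[in_depth]  # (nz_fit, nx, ny)
    zfit = z[in_depth]
    t = confocal_factor(zfit, z_f, z_r)[:, None, None]

    peak = intensity.max(axis=0, keepdims=True)
    usable = intensity > floor_fraction * np.maximum(peak, np.finfo(float).tiny)
    if detect_surface:
        has_tissue = peak[0] >= tissue_peak_fraction * intensity.max()
        above_onset = intensity >= onset_fraction * np.maximum(peak, np.finfo(float).tiny)
        onset_idx = np.argmax(above_onset, axis=0)  # first qualifying bin
        surface_map = zfit[onset_idx]
        surface_map = np.where(has_tissue, surface_map, surface)
        usable &= zfit[:, None, None] >= surface_map[None] + onset_skip_um
    else:
        has_tissue = peak[0] > 0
        surface_map = np.full(intensity.shape[1:], float(surface))
    if max_depth_um is not None:
        usable &= zfit[:, None, None] <= surface_map[None] + max_depth_um
    if detect_surface:
        # keep only the first contiguous tissue segment: once an A-line
        # drops below the floor (tissue exit at the brain edge or block
        # bottom), the edge-response ramp beyond it must not enter the fit;
        # the last bins before the exit are trimmed like the onset ramp
        started = np.logical_or.accumulate(usable, axis=0)
        ended = np.logical_and.accumulate(~(started & ~usable), axis=0)
        usable &= ended
        dz_fit = zfit[1] - zfit[0] if len(zfit) > 1 else 1.0
        trim_bins = int(np.ceil(onset_skip_um / dz_fit))
        if trim_bins > 0:
            tail = np.zeros_like(usable)
            tail[:-trim_bins] = usable[trim_bins:]
            usable &= tail  # drop the trailing trim_bins of each segment
        n_usable = usable.sum(axis=0)
        valid = (n_usable >= min_samples) & has_tissue
    else:
        n_usable = usable.sum(axis=0)
        valid = (n_usable >= min(min_samples, 8)) & has_tissue

    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.log(np.where(usable, intensity, 1.0)) - np.log(t)
    if weighting == "intensity":
        w = np.where(usable, intensity**2, 0.0)
    elif weighting == "uniform":
        w = usable.astype(float)
    else:
        raise ValueError("weighting must be 'intensity' or 'uniform'")
    x = (zfit[:, None, None] - surface_map[None]) * np.ones_like(intensity)

    sw = w.sum(axis=0)
    sw = np.where(sw > 0, sw, 1.0)
    swx = (w * x).sum(axis=0)
    swy = (w * y).sum(axis=0)
    swxx = (w * x * x).sum(axis=0)
    swxy = (w * x * y).sum(axis=0)
    denom = sw * swxx - swx**2
    denom = np.where(np.abs(denom) > 0, denom, np.nan)
    slope = (sw * swxy - swx * swy) / denom  # d(log I')/dz, per um
    intercept = (swy - slope * swx) / sw

    mu = np.clip(-slope * 500.0, 0.0, None)  # -slope/(2e-3): um^-1 -> mm^-1
    i0 = np.exp(intercept)
    resid = y - (intercept[None] + slope[None] * x)
    with np.errstate(invalid="ignore"):
        residual_rms = np.sqrt((w * resid**2).sum(axis=0) / sw)
    valid &= np.isfinite(mu)
    return AttenuationFit(
        mu_mm=np.where(valid, mu, np.nan),
        i0=i0,
        valid=valid,
        residual_rms=residual_rms,
        z_f_um=z_f,
        z_r_um=z_r,
        surface_z_um=surface,
        surface_map_um=surface_map,
    )


def pooled_attenuation_mm(fits: list[AttenuationFit]) -> float:
    """Median attenuation over the valid A-lines of many tiles.

    A brain-level coefficient for depth compensation: robust to individual
    tiles that image little tissue (thin last slice, agarose corners) and
    keeps the compensation gain consistent across the mosaic.
    """
    values = [f.mu_mm[f.valid & np.isfinite(f.mu_mm)] for f in fits]
    pooled = np.concatenate([v.ravel() for v in values]) if values else np.array([])
    if pooled.size == 0:
        raise ValueError("no valid attenuation fits to pool")
    return float(np.median(pooled))


def compensate_depth(
    vol: IntensityVolume,
    fit: AttenuationFit,
    mode: str = "per_aline",
    mu_override_mm: float | None = None,
    mu_fallback_mm: float | None = None,
) -> IntensityVolume:
    """Divide out the confocal envelope and the fitted exponential decay.

    Voxels above the tissue surface are left untouched.  ``mode="per_aline"``
    uses each A-line's own coefficient, which also restores shadows cast by
    strongly attenuating bundles; invalid A-lines fall back to
    ``mu_fallback_mm`` (default: the tile median).  ``mode="median"``
    applies the tile-median coefficient everywhere; ``mu_override_mm``
    forces one coefficient (e.g. a brain-level pooled value).  The output
    is never negative because the compensation is a positive gain.
    """
    z = vol.depth_axis_um
    below = z >= fit.surface_z_um
    fallback = fit.mu_median_mm if mu_fallback_mm is None else float(mu_fallback_mm)
    if mu_override_mm is not None:
        mu = np.full(fit.mu_mm.shape, float(mu_override_mm))
    elif mode == "median":
        mu = np.full(fit.mu_mm.shape, fit.mu_median_mm)
    elif mode == "per_aline":
        mu = np.where(fit.valid, fit.mu_mm, fallback)
    else:
        raise ValueError("mode must be 'per_aline' or 'median'")
    mu = np.where(np.isfinite(mu), mu, 0.0)
    surface = (
        fit.surface_map_um
        if fit.surface_map_um is not None
        else np.full(mu.shape, fit.surface_z_um)
    )
    t = confocal_factor(z[below], fit.z_f_um, fit.z_r_um)[:, None, None]
    depth_in_tissue = np.clip(z[below][:, None, None] - surface[None], 0.0, None)
    decay = np.exp(-2e-3 * mu[None] * depth_in_tissue)
    out = vol.intensity.copy()
    out[below] = vol.intensity[below] / (t * decay)
    return replace(vol, intensity=out)


def compensate_depth_resolved(
    vol: IntensityVolume,
    fit: AttenuationFit,
    mu_reference_mm: float,
    floor_fraction: float = 0.05,
    mu_max_mm: float = 12.0,
) -> IntensityVolume:
    """Two-pass depth-resolved compensation for spatially varying attenuation.

    Pass 1 removes the confocal envelope and a uniform decay at
    ``mu_reference_mm`` (e.g. the brain-level pooled coefficient), giving a
    first reflectivity estimate.  Pass 2 assumes attenuation proportional
    to backscatter (the standard depth-resolved model): the voxelwise
    coefficient is ``mu_reference * R1 / median(R1 over tissue)``, clipped
    to [0, ``mu_max_mm``], integrated cumulatively along each A-line, and
    the original intensity is divided by the confocal envelope and this
    per-A-line decay.  Strongly attenuating bundles then cast no shadow on
    the tissue beneath them, which a single per-A-line exponent cannot
    achieve.
    """
    z = vol.depth_axis_um
    dz = vol.voxel_size_um[0]
    below = z >= fit.surface_z_um
    t = confocal_factor(z[below], fit.z_f_um, fit.z_r_um)[:, None, None]
    first = vol.intensity[below] / t
    decay_ref = np.exp(
        -2e-3 * mu_reference_mm * np.clip(
            z[below][:, None, None]
            - (fit.surface_map_um if fit.surface_map_um is not None else fit.surface_z_um)[None],
            0.0,
            None,
        )
    )
    r1 = first / decay_ref
    amp1 = np.sqrt(np.clip(r1, 0.0, None))
    tissue = amp1 > floor_fraction * amp1.max()
    med = np.median(amp1[tissue]) if tissue.any() else 1.0
    mu_map = np.clip(mu_reference_mm * amp1 / max(med, np.finfo(float).tiny), 0.0, mu_max_mm)
    mu_map = np.where(tissue, mu_map, 0.0)
    cum = np.cumsum(mu_map, axis=0) * dz * 1e-3
    decay = np.exp(-2.0 * np.clip(cum, 0.0, 50.0))
    out = vol.intensity.copy()
    out[below] = first / np.maximum(decay, 1e-12)
    return replace(vol, intensity=out)


# ---------------------------------------------------------------------------
# Focal-stack fusion
# ---------------------------------------------------------------------------

def fuse_focal_stack(vols: list[IntensityVolume]) -> IntensityVolume:
    """Fuse a dynamic-focus stack into one volume by depth-dependent Gaussian
    weighting centred on each member's focal plane.

    The Gaussian half-width at half-maximum equals half the focal-plane
    spacing, so at each focal depth the in-focus member dominates; weights
    are normalized to sum to 1 at every depth (partition of unity).  The
    published dynamic-focus fusion uses modelled defocus kernels in a
    Gabor domain; this depth weighting is a deliberate simplification (see
    docs/methods.md).
    """
    if not vols:
        raise ValueError("need at least one volume")
    if len(vols) == 1:
        return vols[0]
    focal = np.array([v.focal_depth_um for v in vols])
    if not (np.diff(focal) > 0).all():
        raise ValueError("focal depths must be strictly increasing")
    shapes = {v.intensity.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError("all volumes in a stack must share a shape")
    spacing = float(np.diff(focal).mean())
    sigma = (spacing / 2.0) / np.sqrt(2.0 * np.log(2.0))  # HWHM = spacing/2
    z = vols[0].depth_axis_um
    w = np.exp(-0.5 * ((z[None, :] - focal[:, None]) / sigma) ** 2)  # (n_vol, nz)
    w /= w.sum(axis=0, keepdims=True)
    fused = np.zeros_like(vols[0].intensity)
    for wk, v in zip(w, vols):
        fused += wk[:, None, None] * v.intensity
    mid = vols[len(vols) // 2]
    return replace(mid, intensity=fused, focal_depth_um=float(focal.mean()))


def fusion_weights(focal_depths_um: np.ndarray, z_um: np.ndarray) -> np.ndarray:
    """Normalized fusion weights (n_planes, nz) used by :func:`fuse_focal_stack`;
    exposed so the weighting rule itself can be inspected and tested."""
    focal = np.asarray(focal_depths_um, dtype=float)
    if focal.size == 1:
        return np.ones((1, len(z_um)))
    spacing = float(np.diff(focal).mean())
    sigma = (spacing / 2.0) / np.sqrt(2.0 * np.log(2.0))
    w = np.exp(-0.5 * ((np.asarray(z_um)[None, :] - focal[:, None]) / sigma) ** 2)
    return w / w.sum(axis=0, keepdims=True)

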