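"""Stage-coordinate model, phase-correlation calibration, 2-D tile
stitching with distance-transform (diffusion steady-state) blending, and
3-D whole-brain assembly at 25 um isotropic resolution.

Tiles are placed by their *recorded* stage positions converted to Cartesian
micrometres through the affine stage model p = A pM + b; no pairwise
registration is performed.  Blending weights are the normalized distance to
each tile's own boundary, which is the steady state of the diffusion-based
construction: continuous, 1 deep inside a tile's exclusive zone, and a
partition of unity (sum = 1) at every covered pixel.

Resampling convention: pixel centers at half-integer physical coordinates
(pixel i covers [i*px, (i+1)*px), center at (i+0.5)*px), 0-based indices,
linear interpolation for intensity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box

from ._exceptions import DegenerateInputError
from .optics import TileSpec
from .recon import IntensityVolume

__all__ = [
    "StageModel",
    "SliceMosaic",
    "BrainVolume",
    "phase_correlation",
    "calibrate_stage",
    "microsteps_to_cartesian",
    "cartesian_to_microsteps",
    "blend_weights",
    "stitch_slice",
    "assemble_brain",
    "polygon_to_tiles",
]

#: Default depth range (um below the tissue surface) averaged into the AIP.
AIP_DEPTH_UM = 800.0


@dataclass
class StageModel:
    """Affine stage model p = A pM + b mapping microsteps to Cartesian um."""

    A: np.ndarray
    b: np.ndarray
    residual_rms_um: float = 0.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.b = np.asarray(self.b, dtype=float).reshape(2)
        if abs(np.linalg.det(self.A)) < 1e-15:
            raise ValueError("stage transform A must be invertible")

    @classmethod
    def identity(cls) -> "StageModel":
        return cls(np.eye(2), np.zeros(2))


@dataclass
class SliceMosaic:
    """One stitched tissue slice: 3-D volume (z, x, y), 2-D AIP (x, y),
    per-tile blending weights, and placement metadata."""

    volume: np.ndarray
    aip: np.ndarray
    weights: np.ndarray  # (n_tiles, nx, ny)
    origin_um: tuple[float, float]
    pixel_um: float
    dz_um: float
    slice_index: int = 0
    z_um: float = 0.0
    surface_z_um: float = 0.0


@dataclass
class BrainVolume:
    """Assembled whole-sample volume on an isotropic grid (x, y, z)."""

    intensity: np.ndarray
    voxel_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Phase correlation and stage calibration
# ---------------------------------------------------------------------------

def phase_correlation(
    img_a: np.ndarray, img_b: np.ndarray, subpixel: bool = False
) -> tuple[np.ndarray, float]:
    """Translation of ``img_b`` relative to ``img_a`` from the inverse
    transform of the normalized cross-power spectrum.

    Returns (shift, peak):  ``img_b approx img_a`` circularly shifted by
    ``shift`` (row, col).  ``peak`` is the correlation-surface maximum
    (1.0 for an exact circular shift).  Optional 3-point parabolic
    refinement gives subpixel estimates.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("images must be 2-D and of equal shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant image has no phase structure")
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    cross /= np.where(mag > 0, mag, 1.0)
    surface = np.real(np.fft.ifft2(cross))
    idx = np.unravel_index(np.argmax(surface), surface.shape)
    peak = float(surface[idx])
    shift = np.array(idx, dtype=float)
    for axis, size in enumerate(a.shape):
        if shift[axis] > size / 2:
            shift[axis] -= size
    if subpixel:
        for axis, size in enumerate(a.shape):
            i = idx[axis]
            lo = list(idx)
            hi = list(idx)
            lo[axis] = (i - 1) % size
            hi[axis] = (i + 1) % size
            y0, y1, y2 = surface[tuple(lo)], peak, surface[tuple(hi)]
            denom = y0 - 2.0 * y1 + y2
            if denom < 0:
                shift[axis] += 0.5 * (y0 - y2) / denom
    return shift, peak


def calibrate_stage(
    commanded_microsteps: np.ndarray, measured_um: np.ndarray
) -> StageModel:
    """Least-squares fit of p = A pM + b from displacement pairs.

    Needs >= 3 non-collinear microstep positions; raises
    DegenerateInputError on a rank-deficient design.
    """
    pm = np.asarray(commanded_microsteps, dtype=float).reshape(-1, 2)
    p = np.asarray(measured_um, dtype=float).reshape(-1, 2)
    if pm.shape != p.shape or len(pm) < 3:
        raise ValueError("need >= 3 paired displacements")
    design = np.hstack([pm, np.ones((len(pm), 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateInputError("collinear calibration displacements")
    coef, *_ = np.linalg.lstsq(design, p, rcond=None)
    model = StageModel(A=coef[:2].T, b=coef[2])
    resid = p - (pm @ model.A.T + model.b)
    model.residual_rms_um = float(np.sqrt(np.mean(resid**2)))
    return model


def microsteps_to_cartesian(model: StageModel, pm: np.ndarray) -> np.ndarray:
    """Affine map of microstep coordinates to Cartesian um."""
    pm = np.asarray(pm, dtype=float)
    return pm @ model.A.T + model.b


def cartesian_to_microsteps(model: StageModel, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return (p - model.b) @ np.linalg.inv(model.A).T


# ---------------------------------------------------------------------------
# Blending and stitching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MosaicGrid:
    """Target raster: origin (um), shape (pixels), square pixel size (um)."""

    origin_um: tuple[float, float]
    shape: tuple[int, int]
    pixel_um: float

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_um[0] + (np.arange(self.shape[0]) + 0.5) * self.pixel_um
        y = self.origin_um[1] + (np.arange(self.shape[1]) + 0.5) * self.pixel_um
        return x, y


def _grid_for(footprints: list[tuple[float, float, float, float]], pixel_um: float) -> MosaicGrid:
    x0 = min(f[0] for f in footprints)
    y0 = min(f[1] for f in footprints)
    x1 = max(f[2] for f in footprints)
    y1 = max(f[3] for f in footprints)
    nx = max(1, int(round((x1 - x0) / pixel_um)))
    ny = max(1, int(round((y1 - y0) / pixel_um)))
    return MosaicGrid(origin_um=(x0, y0), shape=(nx, ny), pixel_um=pixel_um)


def blend_weights(
    footprints: list[tuple[float, float, float, float]],
    grid: MosaicGrid,
) -> np.ndarray:
    """Per-tile blending weight maps on the target raster.

    ``footprints`` are (x0, y0, x1, y1) rectangles in um.  Each tile's raw
    weight is its Euclidean distance-to-own-boundary (the steady state of
    the diffusion feathering construction); weights are then normalized so
    all covering tiles sum to 1 at every covered pixel.  Uncovered pixels
    get weight 0 from every tile.
    """
    xc, yc = grid.centers()
    inside = np.zeros((len(footprints),) + grid.shape, dtype=bool)
    raw = np.zeros_like(inside, dtype=float)
    for t, (x0, y0, x1, y1) in enumerate(footprints):
        mask = ((xc >= x0) & (xc < x1))[:, None] & ((yc >= y0) & (yc < y1))[None, :]
        inside[t] = mask
        if mask.any():
            raw[t] = ndimage.distance_transform_edt(mask)
    total = raw.sum(axis=0)
    covered = inside.any(axis=0)
    if covered.any() and not np.all(total[covered] > 0):
        # isolated covered pixels with zero distance everywhere: split evenly
        flat = covered & (total == 0)
        n_cov = inside.sum(axis=0)
        raw[:, flat] = inside[:, flat] / np.maximum(n_cov[flat], 1)
        total = raw.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(total > 0, raw / np.where(total > 0, total, 1.0), 0.0)
    return weights


def _resample_tile_plane(
    plane: np.ndarray,
    origin_um: tuple[float, float],
    pixel_um: float,
    grid: MosaicGrid,
    mask: np.ndarray,
) -> np.ndarray:
    """Linear interpolation of one tile plane onto the mosaic pixels in
    ``mask`` (clamped at the tile edge so constant tiles stay constant)."""
    xc, yc = grid.centers()
    gx = (xc - origin_um[0]) / pixel_um - 0.5
    gy = (yc - origin_um[1]) / pixel_um - 0.5
    ii, jj = np.nonzero(mask)
    coords = np.stack([gx[ii], gy[jj]])
    out = np.zeros(grid.shape)
    out[ii, jj] = ndimage.map_coordinates(plane, coords, order=1, mode="nearest")
    return out


def stitch_slice(
    tiles: list[IntensityVolume],
    model: StageModel | None = None,
    pixel_um: float | None = None,
    aip_depth_um: float = AIP_DEPTH_UM,
    slice_index: int = 0,
) -> SliceMosaic:
    """Stitch reconstructed tiles of one slice on their recorded positions.

    If ``model`` is given, tile origins are treated as microsteps and mapped
    through it; otherwise they are already Cartesian um.  Produces the 3-D
    stitched slice, the per-tile weight maps, and the 2-D AIP (mean over the
    first ``aip_depth_um`` below the tissue surface).
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    vs = {t.voxel_size_um for t in tiles}
    if len(vs) != 1:
        raise ValueError("all tiles must share a voxel size")
    dz, px, _ = tiles[0].voxel_size_um
    pixel_um = px if pixel_um is None else pixel_um

    origins = []
    for t in tiles:
        o = np.asarray(t.cartesian_origin_um, dtype=float)
        origins.append(microsteps_to_cartesian(model, o) if model is not None else o)
    footprints = [
        (o[0], o[1], o[0] + t.intensity.shape[1] * px, o[1] + t.intensity.shape[2] * px)
        for o, t in zip(origins, tiles)
    ]
    grid = _grid_for(footprints, pixel_um)
    weights = blend_weights(footprints, grid)
    if not weights.sum(axis=0).all():
        warnings.warn("mosaic has uncovered gaps between tiles")

    nz = min(t.intensity.shape[0] for t in tiles)
    volume = np.zeros((nz,) + grid.shape)
    for t_idx, (tile, origin) in enumerate(zip(tiles, origins)):
        mask = weights[t_idx] > 0
        if not mask.any():
            continue
        for z in range(nz):
            plane = _resample_tile_plane(
                tile.intensity[z], tuple(origin), px, grid, mask
            )
            volume[z] += weights[t_idx] * plane

    surface = tiles[0].surface_z_um
    z_axis = np.arange(nz) * dz
    band = (z_axis >= surface) & (z_axis < surface + aip_depth_um)
    if not band.any():
        band = np.ones(nz, dtype=bool)
    aip = volume[band].mean(axis=0)
    return SliceMosaic(
        volume=volume,
        aip=aip,
        weights=weights,
        origin_um=grid.origin_um,
        pixel_um=pixel_um,
        dz_um=dz,
        slice_index=slice_index,
        z_um=tiles[0].slice_z_um,
        surface_z_um=surface,
    )


# ---------------------------------------------------------------------------
# 3-D assembly
# ---------------------------------------------------------------------------

def slab_weights(extents_um: list[tuple[float, float]], z_um: np.ndarray) -> np.ndarray:
    """1-D feathering weights across overlapping slabs: per-slab distance to
    its own z boundary, normalized to a partition of unity."""
    raw = np.zeros((len(extents_um), len(z_um)))
    for i, (z0, z1) in enumerate(extents_um):
        inside = (z_um >= z0) & (z_um < z1)
        d = np.minimum(z_um - z0, z1 - z_um)
        raw[i] = np.where(inside, np.maximum(d, 1e-9), 0.0)
    total = raw.sum(axis=0)
    return np.where(total > 0, raw / np.where(total > 0, total, 1.0), 0.0)


def assemble_brain(
    slices: list[SliceMosaic],
    voxel_um: float = 25.0,
    usable_depth_um: float | None = None,
) -> BrainVolume:
    """Assemble stitched slices into a single isotropic volume.

    Each slice contributes the depth band from its tissue surface down to
    ``usable_depth_um`` (default: spacing to the next slice plus the actual
    overlap, i.e. everything up to the next contributing surface); axial
    overlaps between consecutive slices are blended with 1-D feathering
    weights that sum to 1.
    """
    if not slices:
        raise ValueError("no slices to assemble")
    z_tops = [s.z_um for s in slices]
    if any(b < a for a, b in zip(z_tops, z_tops[1:])):
        raise ValueError("slices must be ordered by z position")

    extents = []
    for i, s in enumerate(slices):
        nz_avail = s.volume.shape[0]
        max_depth = (nz_avail * s.dz_um) - s.surface_z_um
        if usable_depth_um is not None:
            depth = usable_depth_um
        elif len(slices) > 1:
            # nominal 200 um spacing -> 100 um overlap into the next slice;
            # the last slice reuses the spacing of the previous pair
            spacing = (
                slices[i + 1].z_um - s.z_um
                if i + 1 < len(slices)
                else s.z_um - slices[i - 1].z_um
            )
            depth = spacing * 1.5
        else:
            depth = max_depth
        depth = min(depth, max_depth)
        extents.append((s.z_um, s.z_um + depth))
        if i + 1 < len(slices) and extents[-1][1] < slices[i + 1].z_um:
            warnings.warn("axial gap between consecutive slices")

    x0 = min(s.origin_um[0] for s in slices)
    y0 = min(s.origin_um[1] for s in slices)
    x1 = max(s.origin_um[0] + s.volume.shape[1] * s.pixel_um for s in slices)
    y1 = max(s.origin_um[1] + s.volume.shape[2] * s.pixel_um for s in slices)
    z0 = extents[0][0]
    z1 = max(e[1] for e in extents)
    nx = max(1, int(round((x1 - x0) / voxel_um)))
    ny = max(1, int(round((y1 - y0) / voxel_um)))
    nz = max(1, int(round((z1 - z0) / voxel_um)))
    xg = x0 + (np.arange(nx) + 0.5) * voxel_um
    yg = y0 + (np.arange(ny) + 0.5) * voxel_um
    zg = z0 + (np.arange(nz) + 0.5) * voxel_um

    wz = slab_weights(extents, zg)  # (n_slices, nz)
    out = np.zeros((nx, ny, nz))
    for s, wslab in zip(slices, wz):
        zsel = np.nonzero(wslab > 0)[0]
        if zsel.size == 0:
            continue
        # depth inside this slice volume, from its own cut face
        z_in = (zg[zsel] - s.z_um) + s.surface_z_um
        gz = z_in / s.dz_um - 0.5
        gx = (xg - s.origin_um[0]) / s.pixel_um - 0.5
        gy = (yg - s.origin_um[1]) / s.pixel_um - 0.5
        gzv, gxv, gyv = np.meshgrid(gz, gx, gy, indexing="ij")
        sampled = ndimage.map_coordinates(
            s.volume, np.stack([gzv, gxv, gyv]), order=1, mode="nearest"
        )  # (nzsel, nx, ny)
        out[:, :, zsel] += np.transpose(sampled, (1, 2, 0)) * wslab[zsel][None, None, :]
    return BrainVolume(intensity=out, voxel_um=voxel_um, origin_um=(x0, y0, z0))


# ---------------------------------------------------------------------------
# Polygon to tile grid
# ---------------------------------------------------------------------------

def polygon_to_tiles(
    polyline_um: np.ndarray, tile: TileSpec | None = None
) -> list[tuple[float, float]]:
    """Minimal axis-aligned grid of square tiles covering a closed polygon.

    Tiles of side ``tile.fov_um`` are laid out at stride
    ``tile.stride_um`` from the polygon's bounding-box corner; the grid size
    per axis is ``ceil((span - fov)/stride) + 1`` (at least 1).  Returns the
    (x0, y0) corner of every tile whose footprint intersects the polygon.
    """
    tile = tile or TileSpec()
    pts = np.asarray(polyline_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("polyline must be an (n, 2) array of >= 3 vertices")
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("polygon must be simple (non self-intersecting)")
    x0, y0, x1, y1 = poly.bounds
    fov, stride = tile.fov_um, tile.stride_um

    def n_tiles(span: float) -> int:
        if span <= fov:
            return 1
        return int(math.ceil((span - fov) / stride - 1e-9)) + 1

    nx = n_tiles(x1 - x0)
    ny = n_tiles(y1 - y0)
    corners = []
    for i in range(nx):
        for j in range(ny):
            cx, cy = x0 + i * stride, y0 + j * stride
            if box(cx, cy, cx + fov, cy + fov).intersects(poly):
                corners.append((cx, cy))
    return corners


def polygon_vertices_covered(
    polyline_um: np.ndarray, corners: list[tuple[float, float]], tile: TileSpec
) -> bool:
    """Audit helper: every polygon vertex lies inside >= 1 returned tile."""
    for x, y in np.asarray(polyline_um, dtype=float):
        if not any(
            cx - 1e-9 <= x <= cx + tile.fov_um + 1e-9
            and cy - 1e-9 <= y <= cy + tile.fov_um + 1e-9
            for cx, cy in corners
        ):
            return False
    return True
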