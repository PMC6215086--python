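"""Seeded synthetic ground truth: a digital tissue block, its simulated
swept-source fringes, a multishell diffusion-weighted series with injected
temporal drift, and synthetic dMRI metric maps.

The phantom is an ellipsoidal "brain" embedded in an agarose shell: layered
cortical reflectivity, two bright fiber-bundle ribbons (crossing in one
region), dark tubular vessels, and one ventricle.  Attenuation is higher in
the fiber bundles than in gray matter, zero outside tissue and agarose.
Everything is generated from a single integer seed and is bit-reproducible.

Fringe synthesis inverts the reconstruction model: for every A-line the
ground-truth depth intensity I(z) = R(z) * T(z) * exp(-2 int mu dz') is
computed on the exact DFT depth bins, and the fringe is the sum of cosines
with amplitude sqrt(I) at those bins.  Relative phases across depth are
zero (controllable magnitude, no speckle); each A-line carries one global
carrier phase so the tile-average fringe converges to the common background
term, as it does on the instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .optics import LaserSpec, TileSpec, confocal_factor
from .recon import FringeTile, TilePlacement

__all__ = [
    "Phantom",
    "MetricMaps",
    "make_phantom",
    "ground_truth_intensity",
    "simulate_tile_fringes",
    "simulate_focal_stack",
    "simulate_dwi_series",
    "make_metric_maps",
]


@dataclass
class Phantom:
    """Ground-truth tissue block.  All volumes are (nx, ny, nz) with z depth.

    ``attenuation_mm`` is in mm^-1; masks are booleans; ``atlas_labels`` is a
    small-integer toy ontology in which ``fiber_tract_labels`` play the role
    of the "fiber tracts" category.
    """

    reflectivity: np.ndarray
    attenuation_mm: np.ndarray
    tissue_mask: np.ndarray
    fiber_mask: np.ndarray
    vessel_mask: np.ndarray
    ventricle_mask: np.ndarray
    crossing_mask: np.ndarray
    agarose_mask: np.ndarray
    atlas_labels: np.ndarray
    fiber_tract_labels: tuple[int, ...]
    fiber_orientation: dict[int, tuple[float, float, float]]
    voxel_size_um: float
    seed: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectivity.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * self.voxel_size_um for s in self.shape)


@dataclass
class MetricMaps:
    """Synthetic stand-ins for diffusion metric maps on the phantom grid.
    FA, OD and IC_VF live in [0, 1]; NuFO is a small integer count;
    AFD_max is a nonnegative fODF amplitude."""

    fa: np.ndarray
    nufo: np.ndarray
    afd_max: np.ndarray
    od: np.ndarray
    icvf: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "FA": self.fa,
            "NuFO": self.nufo,
            "AFD_max": self.afd_max,
            "OD": self.od,
            "IC_VF": self.icvf,
        }


# Optical property defaults, mm^-1.  Plausible ex vivo values at 1310 nm:
# gray matter a few mm^-1 below myelinated bundles, agarose nearly clear.
MU_GRAY = 1.5
MU_FIBER = 5.0
MU_VESSEL = 3.0
MU_VENTRICLE = 0.3
MU_AGAROSE = 0.1


def make_phantom(
    shape: tuple[int, int, int] = (96, 96, 64),
    voxel_size_um: float = 12.5,
    seed: int = 0,
) -> Phantom:
    """Generate the digital tissue block.

    Raises ValueError for degenerate shapes (any axis < 16).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError("shape must be a voxel triple with every axis >= 16")
    nx, ny, nz = shape
    rng = np.random.default_rng(seed)

    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    u = (ix - 0.5 * (nx - 1)) / (0.5 * nx)
    v = (iy - 0.5 * (ny - 1)) / (0.5 * ny)
    w = (iz - 0.5 * (nz - 1)) / (0.5 * nz)

    # ellipsoidal brain, slightly below the cut-entry face
    q = (u / 0.80) ** 2 + (v / 0.84) ** 2 + ((w - 0.05) / 0.82) ** 2
    tissue = q <= 1.0
    r_norm = np.sqrt(q)

    # layered cortical reflectivity (thin laminae, ~60 um radial period, so
    # layering averages out over an attenuation-fit window) + a smooth
    # seeded texture field
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    texture /= max(np.abs(texture).max(), 1e-12)
    radius_um = 0.5 * min(nx, ny, nz) * float(voxel_size_um)
    layer_period = max(60.0 / max(radius_um, 1e-9), 1e-3)  # in r_norm units
    reflectivity = np.zeros(shape)
    reflectivity[tissue] = (
        0.30
        + 0.06 * np.sin(2.0 * np.pi * r_norm[tissue] / layer_period)
        + 0.05 * texture[tissue]
    )

    # two fiber ribbons: one running along x, one along y, crossing once
    y_center = ny * (0.42 + 0.08 * np.sin(2.0 * np.pi * ix / nx))
    ribbon1 = (np.abs(iy - y_center) < 3.0) & (np.abs(iz - 0.52 * nz) < 3.0) & tissue
    x_center = nx * (0.55 + 0.06 * np.cos(np.pi * iy / ny))
    ribbon2 = (np.abs(ix - x_center) < 3.0) & (np.abs(iz - 0.50 * nz) < 4.0) & tissue
    fiber = ribbon1 | ribbon2
    crossing = ribbon1 & ribbon2

    # dark tubular vessels, slanted through depth
    vessel = np.zeros(shape, dtype=bool)
    for _ in range(3):
        x0 = rng.uniform(0.25, 0.75) * nx
        y0 = rng.uniform(0.25, 0.75) * ny
        sx = rng.uniform(-0.15, 0.15)
        sy = rng.uniform(-0.15, 0.15)
        r2 = (ix - (x0 + sx * iz)) ** 2 + (iy - (y0 + sy * iz)) ** 2
        vessel |= r2 < 1.8**2
    vessel &= tissue & ~fiber

    # one ventricle (CSF pocket), kept clear of the ribbons
    vent = (
        ((ix - 0.33 * nx) / 7.0) ** 2
        + ((iy - 0.62 * ny) / 8.0) ** 2
        + ((iz - 0.40 * nz) / 6.0) ** 2
    ) <= 1.0
    vent &= tissue
    vent &= ~fiber

    reflectivity[fiber] = 0.75 + 0.04 * texture[fiber]
    reflectivity[vessel] = 0.06
    reflectivity[vent] = 0.03

    attenuation = np.zeros(shape)
    attenuation[tissue] = MU_GRAY
    attenuation[fiber] = MU_FIBER
    attenuation[vessel] = MU_VESSEL
    attenuation[vent] = MU_VENTRICLE

    # agarose embedding shell around the brain; water (mu = 0) beyond
    shell = ndimage.binary_dilation(tissue, iterations=8) & ~tissue
    reflectivity[shell] = 0.02
    attenuation[shell] = MU_AGAROSE
    reflectivity = np.clip(reflectivity, 0.0, 1.0)

    atlas = np.zeros(shape, dtype=np.int16)
    cortex = tissue & (r_norm > 0.62)
    deep = tissue & ~cortex
    atlas[cortex & (u <= 0)] = 1
    atlas[cortex & (u > 0)] = 6
    atlas[deep] = 2
    atlas[vent] = 3
    atlas[ribbon1] = 4
    atlas[ribbon2] = 5

    return Phantom(
        reflectivity=reflectivity,
        attenuation_mm=attenuation,
        tissue_mask=tissue,
        fiber_mask=fiber,
        vessel_mask=vessel,
        ventricle_mask=vent,
        crossing_mask=crossing,
        agarose_mask=shell,
        atlas_labels=atlas,
        fiber_tract_labels=(4, 5),
        fiber_orientation={4: (1.0, 0.0, 0.0), 5: (0.0, 1.0, 0.0)},
        voxel_size_um=float(voxel_size_um),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Fringe simulation
# ---------------------------------------------------------------------------

def _sample_fields(
    phantom: Phantom, x_um: np.ndarray, y_um: np.ndarray, z_um: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear sampling of reflectivity and attenuation at physical
    coordinates (um, phantom frame); zero outside the block."""
    vs = phantom.voxel_size_um
    coords = np.stack(
        np.broadcast_arrays(x_um / vs - 0.5, y_um / vs - 0.5, z_um / vs - 0.5)
    )
    refl = ndimage.map_coordinates(
        phantom.reflectivity, coords, order=1, mode="constant", cval=0.0
    )
    mu = ndimage.map_coordinates(
        phantom.attenuation_mm, coords, order=1, mode="constant", cval=0.0
    )
    return refl, mu


def ground_truth_intensity(
    phantom: Phantom,
    placement: TilePlacement,
    tile: TileSpec,
    laser: LaserSpec,
) -> np.ndarray:
    """Ground-truth depth intensity I(z) on the reconstruction depth bins.

    Shape (n_k/2, n_lat, n_lat).  This is what a perfect (noise-free,
    infinitely resolved) reconstruction of the simulated tile would return;
    round-trip tests compare reconstructions against it.
    """
    dz = laser.depth_bin_um()
    zeta = laser.depth_axis_um()  # depth from zero-delay
    px = tile.pixel_um
    lat = np.arange(tile.n_lat)
    x = placement.x_um + (lat + 0.5) * px
    y = placement.y_um + (lat + 0.5) * px
    # phantom-frame depth of each bin; water standoff above the cut face
    z_phantom = placement.slice_z_um + (zeta - placement.standoff_um)
    xg = x[None, :, None]
    yg = y[None, None, :]
    zg = z_phantom[:, None, None]
    in_sample = (zg >= placement.slice_z_um - 1e-9) * np.ones(
        (len(zeta), tile.n_lat, tile.n_lat)
    )
    refl, mu = _sample_fields(
        phantom,
        np.broadcast_to(xg, in_sample.shape),
        np.broadcast_to(yg, in_sample.shape),
        np.broadcast_to(np.maximum(zg, 0.0), in_sample.shape),
    )
    refl = refl * in_sample
    mu = mu * in_sample
    # round-trip attenuation: 2 * cumulative integral of mu along depth
    optical = np.exp(-2e-3 * np.cumsum(mu, axis=0) * dz)
    t = confocal_factor(zeta, placement.focal_um, tile.rayleigh_range_um)
    return refl * t[:, None, None] * optical


def simulate_tile_fringes(
    phantom: Phantom,
    placement: TilePlacement,
    tile: TileSpec | None = None,
    laser: LaserSpec | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    quantize_12bit: bool = False,
    background_amplitude: float = 4.0,
    speckle: bool = False,
) -> FringeTile:
    """Synthesize raw k-linear fringes for one tile.

    Each A-line is a sum of cosines at the DFT bin frequencies with
    amplitude sqrt(I(z)) plus a common source-envelope background; Gaussian
    noise of sd ``noise_sd * max|fringe|`` is added when requested.
    ``speckle=True`` randomizes per-depth phases (coherent speckle) instead
    of the default zero relative phase.
    """
    tile = tile or TileSpec()
    laser = laser or LaserSpec()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ext = phantom.extent_um
    if placement.x_um >= ext[0] or placement.y_um >= ext[1] or placement.x_um + tile.fov_um <= 0 or placement.y_um + tile.fov_um <= 0:
        raise ValueError("tile footprint does not intersect the phantom")

    rng = np.random.default_rng(seed)
    amp = np.sqrt(ground_truth_intensity(phantom, placement, tile, laser))
    n = laser.n_k_samples
    nbins = n // 2
    # per-A-line global carrier phase; per-depth phases optionally random
    carrier = rng.uniform(0.0, 2.0 * np.pi, size=(1, tile.n_lat, tile.n_lat))
    if speckle:
        phase = rng.uniform(0.0, 2.0 * np.pi, size=amp.shape)
    else:
        # zero spectral phase at band centre (transform-limited): referencing
        # each reflector's cosine to the apodization centre wavelength keeps
        # the window's blur kernel all-positive, so neighbouring depth bins
        # add instead of cancelling and the IFFT magnitude stays controllable
        k = laser.k_grid()
        j_center = (2.0 * np.pi / laser.apod_mu_nm - k[0]) / (k[1] - k[0])
        m = np.arange(nbins)
        phase = (-2.0 * np.pi * j_center * m / n)[:, None, None] * np.ones_like(amp)
    spectrum = np.zeros((n, tile.n_lat, tile.n_lat), dtype=complex)
    spectrum[:nbins] = amp * np.exp(1j * (phase + carrier))
    fringes = np.real(np.fft.ifft(spectrum, axis=0) * n)

    lam = laser.wavelengths_nm()
    background = background_amplitude * np.exp(
        -0.5 * ((lam - laser.lambda0_nm) / (laser.tuning_bandwidth_nm / 4.0)) ** 2
    )
    fringes += background[:, None, None]

    if noise_sd > 0:
        scale = noise_sd * np.abs(fringes).max()
        fringes = fringes + rng.normal(0.0, scale, size=fringes.shape)
    if quantize_12bit:
        lo, hi = fringes.min(), fringes.max()
        span = max(hi - lo, np.finfo(float).tiny)
        fringes = np.round((fringes - lo) / span * 4095.0) / 4095.0 * span + lo
    return FringeTile(
        fringes=fringes, k_grid=laser.k_grid(), placement=placement, laser=laser, tile=tile
    )


def simulate_focal_stack(
    phantom: Phantom,
    xy_center_um: tuple[float, float],
    n_planes: int,
    tile: TileSpec | None = None,
    laser: LaserSpec | None = None,
    seed: int = 0,
    slice_z_um: float = 0.0,
    first_focal_um: float | None = None,
    **kwargs,
) -> list[FringeTile]:
    """Dynamic-focus stack: one tile per focal plane, planes advancing into
    the tissue by ``tile.ocm_z_step_um``.  Planes whose focus would fall
    beyond the bottom of the phantom are dropped with a warning."""
    tile = tile or TileSpec()
    laser = laser or LaserSpec()
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    base = TilePlacement(
        x_um=xy_center_um[0] - tile.fov_um / 2.0,
        y_um=xy_center_um[1] - tile.fov_um / 2.0,
        slice_z_um=slice_z_um,
    )
    z0 = base.standoff_um if first_focal_um is None else first_focal_um
    stack = []
    depth_limit = phantom.extent_um[2] - slice_z_um + base.standoff_um
    for k in range(n_planes):
        focal = z0 + k * tile.ocm_z_step_um
        if focal > depth_limit:
            warnings.warn("focal stack truncated at the bottom of the phantom")
            break
        placement = TilePlacement(
            x_um=base.x_um,
            y_um=base.y_um,
            slice_z_um=slice_z_um,
            standoff_um=base.standoff_um,
            focal_plane_um=focal,
        )
        stack.append(
            simulate_tile_fringes(phantom, placement, tile, laser, seed=seed + k, **kwargs)
        )
    return stack


# ---------------------------------------------------------------------------
# Diffusion series and metric maps
# ---------------------------------------------------------------------------

#: Apparent diffusivities (mm^2/s) used by the DWI simulator; fixed-tissue
#: ex vivo regime: slow parenchyma, faster CSF, anisotropic bundles.
D_GRAY = 0.35e-3
D_CSF = 1.0e-3
D_FIBER_PAR = 0.9e-3
D_FIBER_PERP = 0.15e-3
S0_TISSUE = 100.0
S0_CSF = 300.0


def simulate_dwi_series(
    phantom: Phantom,
    scheme,
    drift: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    voxel_size_um: float = 125.0,
):
    """Simulate the multishell series S_v = S0 exp(-b_v D_app) (1 + drift_v) + noise.

    D_app is isotropic and high in the ventricle (CSF), direction-modulated
    in the fiber ribbons, isotropic and slow elsewhere in tissue; no signal
    outside the brain.  ``drift`` is the per-volume fractional bias (length
    = number of volumes); volumes are ordered by acquisition time.

    The returned series declares 125 um voxels: for diffusion purposes the
    phantom grid is read as a whole-brain-scale object, independent of the
    micrometre OCT geometry.
    """
    from .dmri import DWISeries  # local import to avoid a cycle

    n_vol = len(scheme.bvals)
    if drift is None:
        drift = np.zeros(n_vol)
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (n_vol,):
        raise ValueError("drift length must equal the number of volumes")
    rng = np.random.default_rng(seed)

    s0 = np.zeros(phantom.shape)
    s0[phantom.tissue_mask] = S0_TISSUE
    s0[phantom.ventricle_mask] = S0_CSF

    d_iso = np.zeros(phantom.shape)
    d_iso[phantom.tissue_mask] = D_GRAY
    d_iso[phantom.ventricle_mask] = D_CSF

    signal = np.empty(phantom.shape + (n_vol,), dtype=float)
    fiber_sets = [
        (phantom.atlas_labels == lab, np.array(phantom.fiber_orientation[lab]))
        for lab in phantom.fiber_tract_labels
    ]
    for v in range(n_vol):
        b = scheme.bvals[v]
        g = scheme.bvecs[v]
        adc = d_iso.copy()
        for mask, orient in fiber_sets:
            proj = float(np.dot(g, orient)) ** 2 if b > 0 else 0.0
            adc[mask] = D_FIBER_PERP + (D_FIBER_PAR - D_FIBER_PERP) * proj
        vol = s0 * np.exp(-b * adc) * (1.0 + drift[v])
        signal[..., v] = vol
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd * S0_TISSUE, size=signal.shape)
    signal = np.clip(signal, 0.0, None)
    return DWISeries(
        signal=signal,
        scheme=scheme,
        voxel_size_um=float(voxel_size_um),
        ventricle_mask=phantom.ventricle_mask.copy(),
        brain_mask=phantom.tissue_mask.copy(),
    )


def make_metric_maps(phantom: Phantom, seed: int = 0) -> MetricMaps:
    """Synthetic FA / NuFO / AFD_max / OD / IC_VF maps on the phantom grid.

    FA, AFD_max and IC_VF are elevated in the fiber ribbons, NuFO is 2 in
    the declared crossing region, OD is low in the ribbons; FA, OD, IC_VF
    stay in [0, 1].  Maps are 0 outside tissue.
    """
    rng = np.random.default_rng(seed)

    def smooth_noise(scale: float) -> np.ndarray:
        field = ndimage.gaussian_filter(rng.standard_normal(phantom.shape), sigma=2.0)
        return scale * field / max(np.abs(field).max(), 1e-12)

    tissue = phantom.tissue_mask
    fiber = phantom.fiber_mask
    vent = phantom.ventricle_mask

    fa = np.where(tissue, 0.18, 0.0) + 0.55 * fiber + smooth_noise(0.04)
    fa[vent] = 0.05
    fa = np.clip(fa * tissue, 0.0, 1.0)

    nufo = np.zeros(phantom.shape, dtype=np.int16)
    nufo[tissue] = 1
    nufo[phantom.crossing_mask] = 2
    nufo[vent] = 0

    afd = np.where(tissue, 0.12, 0.0) + 0.40 * fiber + smooth_noise(0.03)
    afd[vent] = 0.04
    afd = np.clip(afd * tissue, 0.0, None)

    od = np.where(tissue, 0.60, 0.0) - 0.40 * fiber + smooth_noise(0.04)
    od = np.clip(od * tissue, 0.0, 1.0)

    icvf = np.where(tissue, 0.35, 0.0) + 0.35 * fiber + smooth_noise(0.04)
    icvf[vent] = 0.05
    icvf = np.clip(icvf * tissue, 0.0, 1.0)

    return MetricMaps(fa=fa, nufo=nufo, afd_max=afd, od=od, icvf=icvf)
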