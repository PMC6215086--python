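"""End-to-end serial-sectioning pipeline on a digital phantom: simulate the
raster of tiles slice by slice, reconstruct, estimate and compensate
attenuation with a brain-level pooled coefficient, stitch each slice, and
assemble the whole block at 25 um isotropic resolution.

This composes the public pieces of :mod:`phantom`, :mod:`recon` and
:mod:`mosaic`; it exists so the reassembly round trip is one call both for
users and for the validation suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import mosaic, phantom as phantom_mod, recon
from .optics import LaserSpec, TileSpec

__all__ = [
    "ReassemblyResult",
    "reconstruct_phantom_brain",
    "phantom_reference",
    "brain_to_reference_grid",
    "reassembly_correlation",
]


@dataclass
class ReassemblyResult:
    brain: mosaic.BrainVolume
    slices: list[mosaic.SliceMosaic]
    pooled_mu_mm: float
    tile_fits: list[recon.AttenuationFit]


def reconstruct_phantom_brain(
    ph: "phantom_mod.Phantom",
    tile_spec: TileSpec | None = None,
    laser: LaserSpec | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    voxel_um: float = 25.0,
    fit_window_um: float = 400.0,
    usable_depth_um: float | None = None,
    compensation: str = "per_aline",
) -> ReassemblyResult:
    """Simulate, reconstruct and assemble the whole phantom block.

    Tiles cover the block laterally at the spec stride (20% overlap);
    slices advance by the spec slice thickness with the standard ~100 um
    imaging overlap into the next slice.  Attenuation is fitted per A-line
    from each A-line's detected tissue onset (uniform log-weights: tissue
    texture is multiplicative) and compensated with the brain-level pooled
    median coefficient, which keeps the gain consistent across tiles that
    image little tissue.
    """
    tile_spec = tile_spec or TileSpec()
    laser = laser or LaserSpec()
    ext = ph.extent_um
    stride = tile_spec.stride_um

    def n_tiles(span: float) -> int:
        if span <= tile_spec.fov_um:
            return 1
        return int(np.ceil((span - tile_spec.fov_um) / stride - 1e-9)) + 1

    nx_t, ny_t = n_tiles(ext[0]), n_tiles(ext[1])
    n_slices = max(1, int(round(ext[2] / tile_spec.slice_thickness_um)))

    raw_slices: list[list[recon.IntensityVolume]] = []
    fits: list[recon.AttenuationFit] = []
    fit_of: list[list[recon.AttenuationFit]] = []
    tile_seed = np.random.default_rng(seed).integers(0, 2**31 - 1)
    counter = 0
    for si in range(n_slices):
        z = si * tile_spec.slice_thickness_um
        vols, vol_fits = [], []
        for i in range(nx_t):
            for j in range(ny_t):
                placement = recon.TilePlacement(
                    x_um=i * stride, y_um=j * stride, slice_z_um=z
                )
                fringes = phantom_mod.simulate_tile_fringes(
                    ph, placement, tile_spec, laser,
                    noise_sd=noise_sd, seed=int(tile_seed) + counter,
                )
                counter += 1
                vol = recon.reconstruct_tile(fringes, reference_mode="smoothed_mean")
                fit = recon.fit_attenuation(
                    vol,
                    max_depth_um=fit_window_um,
                    detect_surface=True,
                    weighting="uniform",
                    floor_fraction=0.05,
                )
                vols.append(vol)
                vol_fits.append(fit)
                fits.append(fit)
        raw_slices.append(vols)
        fit_of.append(vol_fits)

    mu_pooled = recon.pooled_attenuation_mm(fits)
    slices = []
    for si, (vols, vol_fits) in enumerate(zip(raw_slices, fit_of)):
        if compensation == "pooled":
            comp = [
                recon.compensate_depth(v, f, mu_override_mm=mu_pooled)
                for v, f in zip(vols, vol_fits)
            ]
        elif compensation == "per_aline":
            # per-A-line coefficients restore bundle shadows; A-lines whose
            # own fit is invalid use the brain-level pooled coefficient
            comp = [
                recon.compensate_depth(v, f, mode="per_aline", mu_fallback_mm=mu_pooled)
                for v, f in zip(vols, vol_fits)
            ]
        elif compensation == "depth_resolved":
            comp = [
                recon.compensate_depth_resolved(v, f, mu_reference_mm=mu_pooled)
                for v, f in zip(vols, vol_fits)
            ]
        elif compensation == "none":
            comp = vols
        else:
            raise ValueError(
                "compensation must be 'per_aline', 'pooled', 'depth_resolved' or 'none'"
            )
        sm = mosaic.stitch_slice(comp, slice_index=si, aip_depth_um=300.0)
        sm.z_um = si * tile_spec.slice_thickness_um
        slices.append(sm)
    brain = mosaic.assemble_brain(
        slices, voxel_um=voxel_um, usable_depth_um=usable_depth_um
    )
    return ReassemblyResult(
        brain=brain, slices=slices, pooled_mu_mm=mu_pooled, tile_fits=fits
    )


def assemble_ground_truth(
    ph: "phantom_mod.Phantom",
    tile_spec: TileSpec | None = None,
    laser: LaserSpec | None = None,
    voxel_um: float = 25.0,
    usable_depth_um: float | None = None,
) -> mosaic.BrainVolume:
    """Assemble the phantom's *ground-truth* tile intensities through the
    same stitch/assemble machinery (the cut-and-reassemble oracle).

    This is what a perfect reconstruction of the simulated acquisition
    would produce; comparing the real chain against it isolates the fringe
    synthesis, A-line reconstruction, stitching geometry and blending from
    the separately validated attenuation inversion.
    """
    tile_spec = tile_spec or TileSpec()
    laser = laser or LaserSpec()
    ext = ph.extent_um
    stride = tile_spec.stride_um

    def n_tiles(span: float) -> int:
        if span <= tile_spec.fov_um:
            return 1
        return int(np.ceil((span - tile_spec.fov_um) / stride - 1e-9)) + 1

    nx_t, ny_t = n_tiles(ext[0]), n_tiles(ext[1])
    n_slices = max(1, int(round(ext[2] / tile_spec.slice_thickness_um)))
    dz = laser.depth_bin_um()
    px = tile_spec.pixel_um
    slices = []
    for si in range(n_slices):
        z = si * tile_spec.slice_thickness_um
        vols = []
        for i in range(nx_t):
            for j in range(ny_t):
                placement = recon.TilePlacement(
                    x_um=i * stride, y_um=j * stride, slice_z_um=z
                )
                gt = phantom_mod.ground_truth_intensity(ph, placement, tile_spec, laser)
                vols.append(
                    recon.IntensityVolume(
                        intensity=gt,
                        voxel_size_um=(dz, px, px),
                        cartesian_origin_um=(placement.x_um, placement.y_um),
                        focal_depth_um=placement.focal_um,
                        surface_z_um=placement.standoff_um,
                        slice_z_um=z,
                    )
                )
        sm = mosaic.stitch_slice(vols, slice_index=si, aip_depth_um=300.0)
        sm.z_um = z
        slices.append(sm)
    return mosaic.assemble_brain(slices, voxel_um=voxel_um, usable_depth_um=usable_depth_um)


def phantom_reference(
    ph: "phantom_mod.Phantom", voxel_um: float = 25.0
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth reflectivity and tissue mask block-averaged to the
    assembly grid (the fair comparison resolution)."""
    factor = max(1, int(round(voxel_um / ph.voxel_size_um)))
    nx, ny, nz = (s // factor for s in ph.shape)
    crop = ph.reflectivity[: nx * factor, : ny * factor, : nz * factor]
    ref = crop.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))
    tcrop = ph.tissue_mask[: nx * factor, : ny * factor, : nz * factor]
    tis = tcrop.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5)) > 0.5
    return ref, tis


def brain_to_reference_grid(
    brain: mosaic.BrainVolume, shape: tuple[int, int, int], voxel_um: float
) -> np.ndarray:
    """Sample the assembled volume at reference-grid voxel centres."""
    axes = [
        ((np.arange(n) + 0.5) * voxel_um - brain.origin_um[a]) / brain.voxel_um - 0.5
        for a, n in enumerate(shape)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(brain.intensity, np.stack(grid), order=1)


def reassembly_correlation(
    result: ReassemblyResult,
    ph: "phantom_mod.Phantom",
    voxel_um: float = 25.0,
    smooth_sigma_voxels: float = 1.0,
) -> float:
    """Pearson correlation between the assembled volume and the phantom
    reflectivity over tissue, both at the assembly resolution (light
    Gaussian smoothing matches the comparison to the working resolution)."""
    ref, tis = phantom_reference(ph, voxel_um)
    sampled = brain_to_reference_grid(result.brain, ref.shape, voxel_um)
    if smooth_sigma_voxels > 0:
        sampled = ndimage.gaussian_filter(sampled, smooth_sigma_voxels)
        ref = ndimage.gaussian_filter(ref, smooth_sigma_voxels)
    return float(np.corrcoef(sampled[tis], ref[tis])[0, 1])
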