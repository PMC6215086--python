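"""File interchange: NIfTI-1 volumes with micrometre voxel sizes, FSL-style
bval/bvec text tables, fringe-tile containers (npz + JSON sidecar), ROI and
result tables (CSV/JSON), and plain-text 4x4 transforms."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dmri import DWISeries, GradientScheme
from .optics import LaserSpec, TileSpec
from .recon import FringeTile, IntensityVolume, TilePlacement
from .roiselect import ROISpec

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_intensity_volume",
    "save_fringe_tile",
    "load_fringe_tile",
    "save_scheme_fsl",
    "load_scheme_fsl",
    "save_dwi_series",
    "load_dwi_series",
    "save_rois_csv",
    "load_rois_csv",
    "save_rois_json",
    "save_affine_txt",
    "load_affine_txt",
]


def save_nifti(path, data: np.ndarray, voxel_size_um) -> None:
    """Write a volume as NIfTI-1; the header stores voxel sizes in mm."""
    data = np.asarray(data)
    vs = np.atleast_1d(np.asarray(voxel_size_um, dtype=float))
    if vs.size == 1:
        vs = np.repeat(vs, min(data.ndim, 3))
    affine = np.diag(list(vs / 1000.0) + [1.0] * (4 - vs.size))
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(vs / 1000.0) + (1.0,) * (data.ndim - vs.size))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, voxel sizes in um)."""
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3]) * 1000.0
    return np.asarray(img.dataobj, dtype=float), zooms


def save_intensity_volume(path, vol: IntensityVolume) -> None:
    save_nifti(path, vol.intensity, vol.voxel_size_um)


def save_fringe_tile(path, tile: FringeTile) -> None:
    """Binary container: fringes + k-grid in one .npz, acquisition metadata
    in a JSON sidecar next to it."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), fringes=tile.fringes, k_grid=tile.k_grid)
    sidecar = {
        "placement": dataclasses.asdict(tile.placement),
        "laser": dataclasses.asdict(tile.laser),
        "tile": dataclasses.asdict(tile.tile),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_fringe_tile(path) -> FringeTile:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return FringeTile(
        fringes=arrays["fringes"],
        k_grid=arrays["k_grid"],
        placement=TilePlacement(**meta["placement"]),
        laser=LaserSpec(**meta["laser"]),
        tile=TileSpec(**meta["tile"]),
    )


def save_scheme_fsl(prefix, scheme: GradientScheme) -> None:
    """FSL convention: one-row bval file, three-row bvec file."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(prefix.with_suffix(".bvec"), scheme.bvecs.T, fmt="%.8f")


def load_scheme_fsl(bval_path, bvec_path) -> GradientScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    shells = np.unique(bvals[bvals > 0])
    shell_ids = np.full(len(bvals), -1, dtype=int)
    for i, b in enumerate(shells):
        shell_ids[np.isclose(bvals, b)] = i
    return GradientScheme(bvals=bvals, bvecs=bvecs, shell_ids=shell_ids)


def save_dwi_series(prefix, dwi: DWISeries) -> None:
    prefix = Path(prefix)
    save_nifti(prefix.with_suffix(".nii.gz"), dwi.signal, dwi.voxel_size_um)
    save_scheme_fsl(prefix, dwi.scheme)


def load_dwi_series(nifti_path, bval_path, bvec_path) -> DWISeries:
    data, zooms = load_nifti(nifti_path)
    scheme = load_scheme_fsl(bval_path, bvec_path)
    return DWISeries(signal=data, scheme=scheme, voxel_size_um=float(zooms[0]))


def _roi_frame(rois: list[ROISpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "center_x_um": r.center_um[0],
                "center_y_um": r.center_um[1],
                "fov_mm": r.fov_mm,
                "slice_index": r.slice_index,
                "z_first_focal_um": r.z_first_focal_um,
                "ocm_thickness_um": r.ocm_thickness_um,
                "mode": r.mode,
            }
            for r in rois
        ]
    )


def save_rois_csv(path, rois: list[ROISpec]) -> None:
    _roi_frame(rois).to_csv(path, index=False)


def load_rois_csv(path) -> list[ROISpec]:
    df = pd.read_csv(path)
    return [
        ROISpec(
            center_um=(row.center_x_um, row.center_y_um),
            fov_mm=row.fov_mm,
            slice_index=int(row.slice_index),
            z_first_focal_um=row.z_first_focal_um,
            ocm_thickness_um=row.ocm_thickness_um,
            label=int(row.label),
            mode=row.mode,
        )
        for row in df.itertuples()
    ]


def save_rois_json(path, rois: list[ROISpec]) -> None:
    Path(path).write_text(
        json.dumps(_roi_frame(rois).to_dict(orient="records"), indent=2)
    )


def save_affine_txt(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float).reshape(4, 4), fmt="%.10g")


def load_affine_txt(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError("transform file must hold a 4x4 matrix")
    return m
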