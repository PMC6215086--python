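"""Locate high-resolution ROIs in the assembled low-resolution brain and
carry them through given affine transforms to atlas / dMRI space.

Registration *estimation* is out of scope: affine transforms are inputs
(plain 4x4 matrices in physical micrometre coordinates).  What this module
owns is the bookkeeping — normalized cross-correlation template relocation,
rasterizing ROIs into labeled overlay volumes on a brain grid,
nearest-neighbour label resampling through composed affines, per-ROI atlas
structure fractions, and per-ROI metric averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template as _skimage_match_template

from ._exceptions import DataError, DegenerateInputError
from .roiselect import ROISpec

__all__ = [
    "OverlayVolume",
    "AffineTransform",
    "match_template",
    "build_overlay",
    "apply_affine",
    "structure_fractions",
    "roi_metric_average",
]

logger = logging.getLogger(__name__)


@dataclass
class AffineTransform:
    """4x4 homogeneous transform in physical um coordinates."""

    matrix: np.ndarray
    inverse: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-15:
            raise ValueError("singular affine transform")

    def as_forward(self) -> np.ndarray:
        return np.linalg.inv(self.matrix) if self.inverse else self.matrix


@dataclass
class OverlayVolume:
    """Labeled ROI blocks on a brain grid: 0 = background, one small-integer
    label per ROI, plus the label -> ROI table."""

    labels: np.ndarray
    voxel_um: float
    origin_um: tuple[float, float, float]
    roi_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")


# ---------------------------------------------------------------------------
# Template matching
# ---------------------------------------------------------------------------

def match_template(
    slice_aip: np.ndarray,
    roi_image: np.ndarray,
    search_center_px: tuple[int, int] | None = None,
    search_radius_px: int | None = None,
) -> tuple[tuple[int, int], float]:
    """Relocate a high-resolution ROI template inside a slice image.

    Zero-mean normalized cross-correlation over an optional search window
    (centre + radius, in pixels of the slice image, both at the common
    working resolution).  Returns the top-left position of the best match
    and its NCC score in [-1, 1].
    """
    image = np.asarray(slice_aip, dtype=float)
    tmpl = np.asarray(roi_image, dtype=float)
    if np.ptp(tmpl) == 0:
        raise DegenerateInputError("constant template cannot be matched")
    if np.ptp(image) == 0:
        raise DegenerateInputError("constant search image")
    if any(ts > gs for ts, gs in zip(tmpl.shape, image.shape)):
        raise ValueError("template must fit inside the search image")

    r0 = c0 = 0
    window = image
    if search_center_px is not None:
        radius = search_radius_px if search_radius_px is not None else max(image.shape)
        r0 = max(0, search_center_px[0] - radius)
        c0 = max(0, search_center_px[1] - radius)
        r1 = min(image.shape[0], search_center_px[0] + radius + tmpl.shape[0])
        c1 = min(image.shape[1], search_center_px[1] + radius + tmpl.shape[1])
        window = image[r0:r1, c0:c1]
        if any(ts > ws for ts, ws in zip(tmpl.shape, window.shape)):
            raise ValueError("search window smaller than the template")
    ncc = _skimage_match_template(window, tmpl, pad_input=False)
    idx = np.unravel_index(np.argmax(ncc), ncc.shape)
    return (int(idx[0] + r0), int(idx[1] + c0)), float(ncc[idx])


# ---------------------------------------------------------------------------
# Overlay construction and transformation
# ---------------------------------------------------------------------------

def build_overlay(
    rois: list[ROISpec],
    shape: tuple[int, int, int],
    voxel_um: float,
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
    slice_thickness_um: float = 200.0,
) -> OverlayVolume:
    """Rasterize ROIs as axis-aligned blocks into a label volume.

    Lateral footprint: the ROI FOV around its centre.  Axial footprint: from
    ``slice_index * slice_thickness + z_first_focal`` down by the OCM
    thickness.  Later labels overwrite earlier ones on collision (logged).
    """
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    for roi in rois:
        half = roi.fov_um / 2.0
        x0 = int(np.floor((roi.center_um[0] - half - origin_um[0]) / voxel_um))
        x1 = int(np.ceil((roi.center_um[0] + half - origin_um[0]) / voxel_um))
        y0 = int(np.floor((roi.center_um[1] - half - origin_um[1]) / voxel_um))
        y1 = int(np.ceil((roi.center_um[1] + half - origin_um[1]) / voxel_um))
        z_top = roi.slice_index * slice_thickness_um + roi.z_first_focal_um
        z0 = int(np.floor((z_top - origin_um[2]) / voxel_um))
        z1 = int(np.ceil((z_top + roi.ocm_thickness_um - origin_um[2]) / voxel_um))
        x0, y0, z0 = max(x0, 0), max(y0, 0), max(z0, 0)
        x1, y1, z1 = min(x1, shape[0]), min(y1, shape[1]), min(z1, shape[2])
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            logger.warning("ROI label %d falls outside the brain grid", roi.label)
        else:
            block = labels[x0:x1, y0:y1, z0:z1]
            if (block != 0).any():
                logger.warning(
                    "ROI label %d overwrites earlier labels on collision", roi.label
                )
            block[...] = roi.label
        rows.append(
            {
                "label": roi.label,
                "center_x_um": roi.center_um[0],
                "center_y_um": roi.center_um[1],
                "slice_index": roi.slice_index,
                "fov_mm": roi.fov_mm,
                "mode": roi.mode,
            }
        )
    return OverlayVolume(
        labels=labels,
        voxel_um=voxel_um,
        origin_um=origin_um,
        roi_table=pd.DataFrame(rows),
    )


def apply_affine(
    overlay: OverlayVolume,
    transforms: list[AffineTransform],
    target_shape: tuple[int, int, int] | None = None,
    target_voxel_um: float | None = None,
    target_origin_um: tuple[float, float, float] | None = None,
) -> OverlayVolume:
    """Resample the label volume through a sequence of affines.

    The transforms are composed in application order (first listed applied
    first) and the labels are pulled back through the inverse with
    nearest-neighbour interpolation, so no label value is ever invented.
    """
    composed = np.eye(4)
    for t in transforms:
        composed = t.as_forward() @ composed
    inv = np.linalg.inv(composed)

    shape = overlay.labels.shape if target_shape is None else tuple(target_shape)
    voxel = overlay.voxel_um if target_voxel_um is None else float(target_voxel_um)
    origin = overlay.origin_um if target_origin_um is None else tuple(target_origin_um)

    axes = [origin[a] + (np.arange(shape[a]) + 0.5) * voxel for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz, np.ones_like(gx)]).reshape(4, -1)
    src = inv @ pts
    src_idx = [
        (src[a].reshape(shape) - overlay.origin_um[a]) / overlay.voxel_um - 0.5
        for a in range(3)
    ]
    out = ndimage.map_coordinates(
        overlay.labels, np.stack(src_idx), order=0, mode="constant", cval=0
    )
    return replace(
        overlay, labels=out.astype(overlay.labels.dtype), voxel_um=voxel, origin_um=origin
    )


# ---------------------------------------------------------------------------
# Atlas fractions and per-ROI averages
# ---------------------------------------------------------------------------

def structure_fractions(
    overlay: OverlayVolume,
    atlas_labels: np.ndarray,
    fiber_labels: set[int] | tuple[int, ...],
) -> pd.DataFrame:
    """Per-ROI volume fraction of every atlas structure it overlaps, plus a
    flag marking ROIs that touch any fiber-tract structure.

    Rows: (roi_label, atlas_label, fraction, fiber_tract).  Fractions per
    ROI sum to 1.
    """
    atlas = np.asarray(atlas_labels)
    if atlas.shape != overlay.labels.shape:
        raise DataError("overlay and atlas must share a grid")
    fiber = set(int(v) for v in fiber_labels)
    rows = []
    for roi_label in np.unique(overlay.labels):
        if roi_label == 0:
            continue
        sel = overlay.labels == roi_label
        total = int(sel.sum())
        values, counts = np.unique(atlas[sel], return_counts=True)
        is_fiber = any(int(v) in fiber for v in values)
        for v, c in zip(values, counts):
            rows.append(
                {
                    "roi_label": int(roi_label),
                    "atlas_label": int(v),
                    "fraction": c / total,
                    "fiber_tract": is_fiber,
                }
            )
    return pd.DataFrame(rows)


def roi_metric_average(overlay: OverlayVolume, metric: np.ndarray) -> pd.Series:
    """NaN-aware mean of a metric map over each labeled ROI block.

    ROIs without voxels on the grid (or with all-NaN metric) report NaN.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.shape != overlay.labels.shape:
        raise DataError("overlay and metric map must share a grid")
    out = {}
    for roi_label in overlay.roi_table["label"]:
        sel = overlay.labels == roi_label
        vals = metric[sel]
        vals = vals[np.isfinite(vals)]
        out[int(roi_label)] = float(vals.mean()) if vals.size else float("nan")
    return pd.Series(out, name="mean")
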