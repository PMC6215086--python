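"""Automated high-resolution ROI positioning on a stitched slice AIP.

The chain: segment the tissue from the AIP (bilateral denoising, Otsu
threshold, median cleanup, hole filling), build a bias probability map that
favours bright and high-contrast tissue (sum of the min-max normalized AIP
and the normalized deviation from the mean tissue intensity, Gaussian
smoothed, masked, normalized to unit mass), then draw ROI centres without
replacement from that map subject to a margin from the tissue boundary
(250 um) and a minimum centre-to-centre separation.  Selection runs every
fourth slice by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.restoration import denoise_bilateral

from ._exceptions import DegenerateInputError, InfeasibleConstraintsError

__all__ = [
    "TissueMask",
    "ProbabilityMap",
    "ROISpec",
    "segment_tissue",
    "probability_map",
    "candidate_distribution",
    "sample_rois",
    "schedule_rois",
]


@dataclass
class TissueMask:
    mask: np.ndarray
    pixel_um: float
    provenance: dict

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class ProbabilityMap:
    """Nonnegative selection-bias map: zero outside the tissue mask and
    summing to 1 over it."""

    p: np.ndarray
    pixel_um: float
    sigma_um: float


@dataclass
class ROISpec:
    """One high-resolution acquisition target."""

    center_um: tuple[float, float]
    fov_mm: float = 0.5
    slice_index: int = 0
    z_first_focal_um: float = 0.0
    ocm_thickness_um: float = 128.0
    label: int = 1
    mode: str = "auto"

    def __post_init__(self) -> None:
        if self.fov_mm <= 0:
            raise ValueError("fov_mm must be > 0")

    @property
    def fov_um(self) -> float:
        return self.fov_mm * 1000.0


def segment_tissue(
    aip: np.ndarray,
    pixel_um: float = 1.0,
    bilateral_sigma_spatial_px: float = 3.0,
    bilateral_sigma_color: float | None = None,
    median_radius_px: int = 2,
) -> TissueMask:
    """Tissue/background segmentation of a slice AIP.

    Bilateral filter -> Otsu threshold (tissue = bright class) -> median
    filter -> morphological hole filling.  The bilateral range sigma
    defaults to 10% of the dynamic range.
    """
    img = np.asarray(aip, dtype=float)
    if img.ndim != 2:
        raise ValueError("aip must be 2-D")
    span = float(np.ptp(img))
    if span <= 0:
        raise DegenerateInputError("constant image cannot be segmented")
    lo = img.min()
    scaled = (img - lo) / span
    sigma_color = 0.1 if bilateral_sigma_color is None else bilateral_sigma_color / span
    den = denoise_bilateral(
        scaled, sigma_color=sigma_color, sigma_spatial=bilateral_sigma_spatial_px
    )
    thr = threshold_otsu(den)
    mask = den > thr
    mask = median_filter(mask, disk(median_radius_px)).astype(bool)
    mask = ndimage.binary_fill_holes(mask)
    return TissueMask(
        mask=mask,
        pixel_um=pixel_um,
        provenance={
            "otsu_threshold": float(thr),
            "bilateral_sigma_spatial_px": bilateral_sigma_spatial_px,
            "bilateral_sigma_color": sigma_color,
            "median_radius_px": median_radius_px,
        },
    )


def _norm01(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max normalization using the value range inside the mask; a
    constant field maps to zeros."""
    inside = values[mask]
    span = float(np.ptp(inside)) if inside.size else 0.0
    if span <= 0:
        return np.zeros_like(values)
    return (values - inside.min()) / span


def probability_map(
    aip: np.ndarray, mask: TissueMask, sigma_um: float = 75.0
) -> ProbabilityMap:
    """Selection-bias map from the AIP and the tissue mask.

    f = norm01(aip) + norm01(|aip - mean(aip over mask)|), Gaussian-smoothed
    with sigma = ``sigma_um`` (smoothing before masking), zeroed outside the
    mask, and normalized to unit mass over it.  If the AIP is constant over
    the tissue the map degenerates to the uniform distribution on the mask.
    Invariant to affine rescaling of the AIP because both features are
    min-max normalized.
    """
    img = np.asarray(aip, dtype=float)
    m = mask.mask
    if not m.any():
        raise ValueError("empty tissue mask")
    mean_in = img[m].mean()
    f = _norm01(img, m) + _norm01(np.abs(img - mean_in), m)
    sigma_px = sigma_um / mask.pixel_um
    f = ndimage.gaussian_filter(f, sigma=sigma_px)
    f = np.where(m, np.clip(f, 0.0, None), 0.0)
    total = f.sum()
    if total <= 0:
        f = m.astype(float)
        total = f.sum()
    return ProbabilityMap(p=f / total, pixel_um=mask.pixel_um, sigma_um=sigma_um)


def candidate_distribution(
    pmap: ProbabilityMap, mask: TissueMask, margin_um: float = 250.0
) -> tuple[np.ndarray, np.ndarray]:
    """Valid ROI centre pixels (N, 2 index array) and their normalized
    selection probabilities.

    Candidates are tissue pixels at least ``margin_um`` from the
    tissue/background boundary (Euclidean distance transform of the mask).
    """
    dist = ndimage.distance_transform_edt(mask.mask) * mask.pixel_um
    eroded = dist >= margin_um
    idx = np.argwhere(eroded)
    if idx.size == 0:
        return idx, np.zeros(0)
    probs = pmap.p[eroded]
    total = probs.sum()
    if total <= 0:
        probs = np.ones(len(idx)) / len(idx)
    else:
        probs = probs / total
    return idx, probs


def sample_rois(
    pmap: ProbabilityMap,
    mask: TissueMask,
    n: int,
    margin_um: float = 250.0,
    min_separation_um: float = 0.0,
    seed: int = 0,
    fov_mm: float = 0.5,
    slice_index: int = 0,
    max_attempts_per_roi: int = 100,
) -> list[ROISpec]:
    """Draw up to ``n`` ROI centres from the probability map.

    Probability-weighted draws without replacement; candidates closer than
    ``min_separation_um`` (centre-to-centre) to an accepted ROI are
    rejected.  Deterministic given the seed.  Returns fewer than ``n`` ROIs
    with a warning when the constraints exhaust the candidates; raises
    InfeasibleConstraintsError when the margin leaves no candidate at all.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    idx, probs = candidate_distribution(pmap, mask, margin_um)
    if len(idx) == 0:
        raise InfeasibleConstraintsError(
            "margin of %g um leaves no candidate ROI position" % margin_um
        )
    rng = np.random.default_rng(seed)
    px = pmap.pixel_um
    accepted: list[tuple[float, float]] = []
    rois: list[ROISpec] = []
    available = np.ones(len(idx), dtype=bool)
    attempts = 0
    max_attempts = max_attempts_per_roi * n
    while len(rois) < n and attempts < max_attempts:
        attempts += 1
        p = np.where(available, probs, 0.0)
        total = p.sum()
        if total <= 0:
            break
        pick = int(rng.choice(len(idx), p=p / total))
        available[pick] = False
        cx = (idx[pick][0] + 0.5) * px
        cy = (idx[pick][1] + 0.5) * px
        if min_separation_um > 0 and any(
            np.hypot(cx - ax, cy - ay) < min_separation_um for ax, ay in accepted
        ):
            continue
        accepted.append((cx, cy))
        rois.append(
            ROISpec(
                center_um=(cx, cy),
                fov_mm=fov_mm,
                slice_index=slice_index,
                label=len(rois) + 1,
                mode="auto",
            )
        )
    if len(rois) < n:
        warnings.warn(
            "constraints exhausted candidates: %d of %d ROIs placed" % (len(rois), n)
        )
    return rois


def schedule_rois(slice_index: int, every: int = 4) -> bool:
    """True on slices where automatic ROI selection runs (every 4th slice)."""
    if every <= 0:
        raise ValueError("every must be a positive integer")
    if slice_index < 0:
        raise ValueError("slice_index must be >= 0")
    return slice_index % every == 0
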