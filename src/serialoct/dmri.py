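"""Multishell diffusion scheme handling, CSF-anchored temporal drift
compensation for ex vivo series, and the data-driven NuFO threshold rule.

Drift model: fixed samples equilibrate thermally during long acquisitions,
which slowly changes water diffusivity and hence the measured signal.  The
cerebrospinal fluid is isotropic, so within one shell its mean signal should
be constant over time; the drift is estimated as the difference between the
measured CSF time profile and a synthetic profile that is constant within
each shell, smoothed temporally (Gaussian, sigma = 1 subscan), and removed
additively from every voxel.

Tensor/fODF/NODDI model fitting is deliberately not reimplemented: metric
maps enter from the phantom generator or from user-supplied files.  The
ex vivo NODDI settings used with such maps (d_iso = 1.0e-3 mm^2/s,
d_par = 0.6e-3 mm^2/s, lambda1 = 0.5, lambda2 = 1.0e-3) are recorded as
configuration metadata only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "GradientScheme",
    "DWISeries",
    "DriftProfile",
    "NODDI_EX_VIVO_CONFIG",
    "build_scheme",
    "fibonacci_sphere",
    "voxel_size_from_fov",
    "segment_ventricles",
    "estimate_drift",
    "compensate_drift",
    "nufo_from_peaks",
]

#: Recorded ex vivo NODDI configuration (metadata, not used in computation).
NODDI_EX_VIVO_CONFIG = {
    "d_iso_mm2_s": 1.0e-3,
    "d_par_mm2_s": 0.6e-3,
    "lambda1": 0.5,
    "lambda2": 1.0e-3,
    "ex_vivo_dot_compartment": True,
}


@dataclass
class GradientScheme:
    """Per-volume b-values (s/mm^2), unit b-vectors, and shell ids in
    acquisition order.  b = 0 volumes carry a zero vector and shell id -1."""

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.shell_ids = np.asarray(self.shell_ids, dtype=int)
        if self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvecs must be (n_volumes, 3)")
        b0 = self.bvals == 0
        if not np.allclose(self.bvecs[b0], 0.0):
            raise ValueError("b=0 volumes must have zero vectors")
        norms = np.linalg.norm(self.bvecs[~b0], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("nonzero b-vectors must be unit norm")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def shells(self) -> np.ndarray:
        """Distinct nonzero b-values, ascending."""
        return np.unique(self.bvals[~self.is_b0])


@dataclass
class DWISeries:
    """4-D diffusion series: signal (x, y, z, volume) in acquisition order."""

    signal: np.ndarray
    scheme: GradientScheme
    voxel_size_um: float = 125.0
    ventricle_mask: np.ndarray | None = None
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4 or self.signal.shape[3] != len(self.scheme):
            raise ValueError("signal must be 4-D with one volume per scheme entry")
        if (self.signal < 0).any():
            raise ValueError("signal must be nonnegative")


@dataclass
class DriftProfile:
    """Per-volume additive drift estimate, in signal units."""

    values: np.ndarray
    sigma_subscan: float = 1.0
    n_voxels_used: int = 0
    seed: int = 0
    measured: np.ndarray | None = field(default=None, repr=False)
    synthetic: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


# ---------------------------------------------------------------------------
# Scheme construction
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int, seed: int = 0) -> np.ndarray:
    """n quasi-uniform unit directions from the Fibonacci spiral, rotated by
    a seeded random rotation (a deterministic stand-in for electrostatic-
    repulsion direction optimization; see docs/methods.md)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    cos_theta = 1.0 - 2.0 * i / n
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, 1.0))
    dirs = np.column_stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
    )
    rng = np.random.default_rng(seed)
    q = rng.standard_normal((3, 3))
    rot, _ = np.linalg.qr(q)
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    return dirs @ rot.T


def build_scheme(
    n_per_shell: list[int] = (6, 15, 42),
    b_values: list[float] = (400.0, 1066.0, 2000.0),
    n_b0: int = 7,
    seed: int = 0,
) -> GradientScheme:
    """Multishell scheme: quasi-uniform directions per shell, shells laid
    out in blocks of ascending b, with b = 0 volumes interlaced evenly
    across the acquisition order."""
    n_per_shell = list(n_per_shell)
    b_values = list(b_values)
    if len(n_per_shell) != len(b_values):
        raise ValueError("n_per_shell and b_values must have the same length")
    if any(n < 0 for n in n_per_shell) or n_b0 < 0:
        raise ValueError("counts must be nonnegative")

    dw_bvals: list[float] = []
    dw_bvecs: list[np.ndarray] = []
    dw_shell: list[int] = []
    for shell_idx, (n, b) in enumerate(zip(n_per_shell, b_values)):
        if n == 0:
            continue
        dirs = fibonacci_sphere(n, seed=seed + shell_idx)
        dw_bvals.extend([b] * n)
        dw_bvecs.extend(dirs)
        dw_shell.extend([shell_idx] * n)

    total = len(dw_bvals) + n_b0
    b0_slots = set(
        int(round(p)) for p in np.linspace(0, total - 1, n_b0)
    ) if n_b0 else set()
    bvals = np.zeros(total)
    bvecs = np.zeros((total, 3))
    shells = np.full(total, -1, dtype=int)
    dw_iter = iter(range(len(dw_bvals)))
    for pos in range(total):
        if pos in b0_slots:
            continue
        i = next(dw_iter)
        bvals[pos] = dw_bvals[i]
        bvecs[pos] = dw_bvecs[i]
        shells[pos] = dw_shell[i]
    return GradientScheme(bvals=bvals, bvecs=bvecs, shell_ids=shells)


def voxel_size_from_fov(
    fov_mm: tuple[float, float, float] = (16.0, 12.0, 8.0),
    matrix: tuple[int, int, int] = (128, 96, 64),
) -> tuple[float, float, float]:
    """Voxel size in micrometres from an imaging FOV and acquisition matrix."""
    return tuple(1000.0 * f / m for f, m in zip(fov_mm, matrix))


# ---------------------------------------------------------------------------
# Drift estimation / compensation
# ---------------------------------------------------------------------------

def segment_ventricles(
    b0: np.ndarray, quantile: float = 0.99, brain_mask: np.ndarray | None = None
) -> np.ndarray:
    """CSF mask: voxels above the given intensity quantile of the b0 image
    (quantile taken within the brain mask when one is provided)."""
    vol = np.asarray(b0, dtype=float)
    if np.ptp(vol) == 0:
        raise ValueError("constant b0 image")
    if brain_mask is not None:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        ref = vol[brain_mask]
    else:
        ref = vol.ravel()
    thr = np.quantile(ref, quantile)
    mask = vol >= thr if quantile > 0 else np.ones_like(vol, dtype=bool)
    if brain_mask is not None:
        mask &= brain_mask
    if not mask.any():
        raise RuntimeError("ventricle segmentation produced an empty mask")
    return mask


def _smooth_linear_boundary(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with linear-extrapolated padding.

    A plain boundary mode (nearest/reflect) biases the endpoints of a
    trending series; padding with the end slopes keeps the filter unbiased
    on linear drifts, which is exactly the regime the compensation targets.
    """
    values = np.asarray(values, dtype=float)
    m = len(values)
    if m < 2:
        return values.copy()
    pad = max(int(np.ceil(4.0 * sigma)), 1)
    k = min(m, 3)
    x = np.arange(k)
    left = np.polyfit(x, values[:k], 1)
    right = np.polyfit(x, values[-k:], 1)
    left_ext = np.polyval(left, np.arange(-pad, 0))
    right_ext = np.polyval(right, np.arange(k, k + pad))
    padded = np.concatenate([left_ext, values, right_ext])
    out = ndimage.gaussian_filter1d(padded, sigma=sigma, mode="nearest")
    return out[pad : pad + m]


def estimate_drift(
    dwi: DWISeries,
    csf_mask: np.ndarray | None = None,
    n_voxels: int = 1000,
    sigma_subscan: float = 1.0,
    seed: int = 0,
) -> DriftProfile:
    """Estimate the additive temporal drift from the CSF signal.

    measured(t): mean signal over ``n_voxels`` randomly chosen CSF voxels,
    per volume.  synthetic(t): the per-shell mean of measured, constant
    within each shell (b = 0 treated as its own shell).  drift(t) =
    measured - synthetic, Gaussian-smoothed along time with
    sigma = ``sigma_subscan`` volumes (0 disables smoothing).

    Smoothing is applied within each shell's own subseries: the raw drift
    is scaled by the shell signal level, so a filter that crossed shell
    boundaries would smear the large b = 0 excursions onto neighbouring
    high-b volumes instead of suppressing estimation noise.
    """
    mask = dwi.ventricle_mask if csf_mask is None else np.asarray(csf_mask, dtype=bool)
    if mask is None or not mask.any():
        raise ValueError("empty CSF mask")
    coords = np.argwhere(mask)
    rng = np.random.default_rng(seed)
    if len(coords) < n_voxels:
        warnings.warn(
            "CSF mask has %d voxels (< %d requested); using all" % (len(coords), n_voxels)
        )
        chosen = coords
    else:
        chosen = coords[rng.choice(len(coords), size=n_voxels, replace=False)]
    measured = dwi.signal[chosen[:, 0], chosen[:, 1], chosen[:, 2], :].mean(axis=0)

    shell_of = np.where(dwi.scheme.is_b0, -1, dwi.scheme.shell_ids)
    synthetic = np.empty_like(measured)
    for s in np.unique(shell_of):
        sel = shell_of == s
        synthetic[sel] = measured[sel].mean()
    drift = measured - synthetic
    if sigma_subscan > 0:
        smoothed = np.empty_like(drift)
        for s in np.unique(shell_of):
            sel = shell_of == s
            smoothed[sel] = _smooth_linear_boundary(drift[sel], sigma_subscan)
        drift = smoothed
    return DriftProfile(
        values=drift,
        sigma_subscan=sigma_subscan,
        n_voxels_used=len(chosen),
        seed=seed,
        measured=measured,
        synthetic=synthetic,
    )


def compensate_drift(
    dwi: DWISeries, drift: DriftProfile, multiplicative: bool = False
) -> DWISeries:
    """Remove the estimated drift from every voxel.

    Default convention subtracts the measured-minus-synthetic excess (the
    compensation that cancels the estimate); ``multiplicative=True`` instead
    rescales each volume by synthetic/measured ratios derived from the
    drift.  Corrected signal is clipped at 0.
    """
    if len(drift.values) != len(dwi.scheme):
        raise ValueError("drift length must match the number of volumes")
    if multiplicative:
        if drift.measured is None or drift.synthetic is None:
            raise ValueError("multiplicative correction needs measured/synthetic profiles")
        ratio = drift.synthetic / np.where(drift.measured > 0, drift.measured, 1.0)
        corrected = dwi.signal * ratio[None, None, None, :]
    else:
        corrected = dwi.signal - drift.values[None, None, None, :]
    return replace(dwi, signal=np.clip(corrected, 0.0, None))


# ---------------------------------------------------------------------------
# NuFO thresholding
# ---------------------------------------------------------------------------

def nufo_from_peaks(
    peak_amplitudes: np.ndarray, ventricle_afd: np.ndarray
) -> np.ndarray:
    """Number of fiber orientations per voxel from fODF peak amplitudes.

    The data-driven threshold is 1.5x the mean AFD_max in the ventricles;
    NuFO counts the peaks at or above it.  ``peak_amplitudes`` is
    (n_voxels, max_peaks), zero-padded.
    """
    amps = np.atleast_2d(np.asarray(peak_amplitudes, dtype=float))
    ref = np.asarray(ventricle_afd, dtype=float)
    if ref.size == 0:
        raise ValueError("ventricle reference must be nonempty")
    if (amps < 0).any():
        raise ValueError("peak amplitudes must be nonnegative")
    threshold = 1.5 * ref.mean()
    return (amps >= threshold).sum(axis=1).astype(int)
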