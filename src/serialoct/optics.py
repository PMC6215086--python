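"""Swept-source and tile-geometry descriptions shared by the simulator and
the reconstruction chain.

Conventions used throughout the package
---------------------------------------
* x, y are the lateral (stage-plane) axes, z is depth increasing into the
  sample.  All physical lengths are micrometres unless a name says otherwise.
* Interference fringes are sampled on a k-grid that is strictly linear in
  wavenumber, ascending, spanning the source tuning bandwidth.
* The depth axis of a reconstructed A-line follows the discrete-Fourier
  relation: one axial bin corresponds to an optical-path step of
  ``2*pi / (N * dk)``; physical depth divides this by 2 (double pass) and by
  the refractive index of the immersion/tissue medium (1.33, water).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Group refractive index used for the optical-path -> physical-depth
#: conversion (water / hydrated tissue).
REFRACTIVE_INDEX = 1.33


@dataclass(frozen=True)
class LaserSpec:
    """Swept-source description: a 1310 nm centre wavelength with a 100 nm
    tuning bandwidth, sampled linearly in wavenumber, and a Gaussian
    spectral apodization window expressed in wavelength."""

    lambda0_nm: float = 1310.0
    tuning_bandwidth_nm: float = 100.0
    n_k_samples: int = 512
    apod_mu_nm: float = 1310.0
    apod_sigma_nm: float = 20.0

    def __post_init__(self) -> None:
        if self.apod_sigma_nm <= 0:
            raise ValueError("apod_sigma_nm must be > 0")
        if self.tuning_bandwidth_nm <= 0:
            raise ValueError("tuning_bandwidth_nm must be > 0")
        if self.n_k_samples < 8 or self.n_k_samples % 2:
            raise ValueError("n_k_samples must be an even integer >= 8")

    @property
    def lambda_min_nm(self) -> float:
        return self.lambda0_nm - self.tuning_bandwidth_nm / 2.0

    @property
    def lambda_max_nm(self) -> float:
        return self.lambda0_nm + self.tuning_bandwidth_nm / 2.0

    def k_grid(self) -> np.ndarray:
        """Ascending, uniform wavenumber samples k = 2*pi/lambda in 1/nm."""
        k_min = 2.0 * np.pi / self.lambda_max_nm
        k_max = 2.0 * np.pi / self.lambda_min_nm
        return np.linspace(k_min, k_max, self.n_k_samples)

    def wavelengths_nm(self) -> np.ndarray:
        """Wavelength of each k-sample (descending as k ascends)."""
        return 2.0 * np.pi / self.k_grid()

    def apodization_window(self, wavelengths_nm: np.ndarray | None = None) -> np.ndarray:
        """Peak-normalized Gaussian spectral window, evaluated in wavelength
        and resampled onto the k-grid.  Equals 1 at ``apod_mu_nm`` and
        exp(-1/2) one ``apod_sigma_nm`` away."""
        lam = self.wavelengths_nm() if wavelengths_nm is None else np.asarray(wavelengths_nm)
        return np.exp(-0.5 * ((lam - self.apod_mu_nm) / self.apod_sigma_nm) ** 2)

    def depth_bin_um(self) -> float:
        """Physical axial bin spacing of a reconstructed A-line (in tissue)."""
        k = self.k_grid()
        dk = k[1] - k[0]
        optical_path_nm = 2.0 * np.pi / (self.n_k_samples * dk)
        return optical_path_nm / (2.0 * REFRACTIVE_INDEX) / 1000.0

    def depth_axis_um(self) -> np.ndarray:
        """Depth of each retained axial bin (Hermitian half-range)."""
        return np.arange(self.n_k_samples // 2) * self.depth_bin_um()


@dataclass(frozen=True)
class TileSpec:
    """Acquisition geometry of one OCT tile and of the serial sectioning.

    fov_mm            lateral field of view of a square tile (0.5 mm)
    overlap_fraction  lateral overlap between neighbouring tiles (0.2)
    n_lat             lateral A-lines per axis
    slice_thickness_um  vibratome slice thickness (200 um)
    ocm_z_step_um     axial spacing of dynamic-focus volumes (16 um)
    interface_scan_step_um  coarse axial step of the interface search (50 um)
    rayleigh_range_um apparent Rayleigh range of the confocal axial envelope
    """

    fov_mm: float = 0.5
    overlap_fraction: float = 0.2
    n_lat: int = 24
    slice_thickness_um: float = 200.0
    ocm_z_step_um: float = 16.0
    interface_scan_step_um: float = 50.0
    rayleigh_range_um: float = 150.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.fov_mm <= 0 or self.n_lat < 2:
            raise ValueError("fov_mm must be > 0 and n_lat >= 2")
        if self.stride_um <= 0:
            raise ValueError("tile stride must be > 0")

    @property
    def fov_um(self) -> float:
        return self.fov_mm * 1000.0

    @property
    def stride_um(self) -> float:
        """Lateral distance between neighbouring tile origins."""
        return self.fov_um * (1.0 - self.overlap_fraction)

    @property
    def pixel_um(self) -> float:
        return self.fov_um / self.n_lat


def confocal_factor(z_um: np.ndarray | float, focal_z_um: float, rayleigh_um: float) -> np.ndarray:
    """Axial confocal sensitivity envelope T(z) = [((z - z_f)/z_r)^2 + 1]^-1.

    The standard single-mode fibre detection form; peaks at the focal depth
    and decays as a Lorentzian with the apparent Rayleigh range ``z_r``.
    """
    if rayleigh_um <= 0:
        raise ValueError("rayleigh_um must be > 0")
    z = np.asarray(z_um, dtype=float)
    return 1.0 / (((z - focal_z_um) / rayleigh_um) ** 2 + 1.0)
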