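"""A-line reconstruction, apodization, attenuation fitting/compensation,
and focal-stack fusion."""

import numpy as np
import pytest

from serialoct import recon
from serialoct.optics import confocal_factor
from serialoct.recon import AttenuationFit, IntensityVolume


def make_profile_volume(laser, mu_mm, i0=1.0, surface=100.0, z_f=100.0, z_r=150.0,
                        n_lat=3, noise_sd=0.0, rng=None):
    """Volume of identical single-scattering + confocal A-lines."""
    z = laser.depth_axis_um()
    profile = i0 * confocal_factor(z, z_f, z_r) * np.exp(
        -2e-3 * mu_mm * np.clip(z - surface, 0.0, None)
    )
    profile = np.where(z >= surface, profile, 1e-12)
    vol = np.tile(profile[:, None, None], (1, n_lat, n_lat))
    if noise_sd > 0:
        vol = np.clip(vol + rng.normal(0.0, noise_sd * vol.max(), vol.shape), 1e-15, None)
    return IntensityVolume(
        intensity=vol,
        voxel_size_um=(laser.depth_bin_um(), 20.0, 20.0),
        focal_depth_um=z_f,
        surface_z_um=surface,
    )


class TestReconstructAline:
    def test_fringe_equal_to_reference_gives_zero(self, laser):
        f = np.sin(np.arange(laser.n_k_samples))
        assert np.allclose(recon.reconstruct_aline(f, f, laser), 0.0)

    def test_apodization_window_values(self, laser):
        """Gaussian window: 1.0 at the centre wavelength, exp(-1/2) one sigma away."""
        w_mu = laser.apodization_window(np.array([laser.apod_mu_nm]))
        w_sigma = laser.apodization_window(
            np.array([laser.apod_mu_nm + laser.apod_sigma_nm])
        )
        assert w_mu[0] == pytest.approx(1.0, abs=1e-12)
        assert w_sigma[0] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_cosine_fringe_peaks_at_reflector_depth(self, laser):
        """cos(k * 2 n z0) peaks at the bin nearest z0 = 100 um (oracle:
        direct evaluation of the DFT bin grid)."""
        from serialoct.optics import REFRACTIVE_INDEX

        z0 = 100.0
        k = laser.k_grid()
        fringe = np.cos(k * 2.0 * REFRACTIVE_INDEX * z0 * 1000.0)  # k in 1/nm
        profile = recon.reconstruct_aline(fringe, np.zeros_like(fringe), laser)
        dz = laser.depth_bin_um()
        assert abs(int(np.argmax(profile)) - round(z0 / dz)) <= 1

    def test_length_mismatch_rejected(self, laser):
        with pytest.raises(ValueError):
            recon.reconstruct_aline(np.zeros(10), np.zeros(12), laser)

    def test_amplitude_scaling_quadratic(self, laser):
        """Parseval-style sanity: doubling the fringe doubles the amplitude,
        quadrupling the reconstructed intensity."""
        rng = np.random.default_rng(0)
        fringe = rng.standard_normal(laser.n_k_samples)
        ref = np.zeros_like(fringe)
        p1 = recon.reconstruct_aline(fringe, ref, laser)
        p2 = recon.reconstruct_aline(2.0 * fringe, ref, laser)
        assert np.allclose(p2, 4.0 * p1, rtol=1e-9)


class TestReconstructTile:
    def test_identical_fringes_reconstruct_to_zero(self, laser, tile_spec):
        fringe = np.sin(0.3 * np.arange(laser.n_k_samples))
        tile = recon.FringeTile(
            fringes=np.tile(fringe[:, None, None], (1, 4, 4)),
            k_grid=laser.k_grid(),
            placement=recon.TilePlacement(x_um=0, y_um=0),
            laser=laser,
            tile=tile_spec,
        )
        vol = recon.reconstruct_tile(tile)
        assert np.allclose(vol.intensity, 0.0)

    def test_output_is_hermitian_half_range(self, laser, tile_spec):
        rng = np.random.default_rng(0)
        tile = recon.FringeTile(
            fringes=rng.standard_normal((laser.n_k_samples, 4, 4)),
            k_grid=laser.k_grid(),
            placement=recon.TilePlacement(x_um=0, y_um=0),
            laser=laser,
            tile=tile_spec,
        )
        vol = recon.reconstruct_tile(tile)
        assert vol.intensity.shape[0] == laser.n_k_samples // 2
        assert (vol.intensity >= 0).all()
        assert np.isfinite(vol.intensity).all()

    def test_non_finite_fringes_raise_data_error(self, laser, tile_spec):
        from serialoct._exceptions import DataError

        bad = np.zeros((laser.n_k_samples, 4, 4))
        bad[5, 1, 1] = np.nan
        tile = recon.FringeTile(
            fringes=bad,
            k_grid=laser.k_grid(),
            placement=recon.TilePlacement(x_um=0, y_um=0),
            laser=laser,
            tile=tile_spec,
        )
        with pytest.raises(DataError):
            recon.reconstruct_tile(tile)


class TestAttenuationFit:
    @pytest.mark.parametrize("mu", [1.0, 2.0, 4.0, 8.0])
    def test_noiseless_recovery_within_one_percent(self, laser, mu):
        vol = make_profile_volume(laser, mu)
        fit = recon.fit_attenuation(vol, max_depth_um=400.0)
        assert fit.mu_median_mm == pytest.approx(mu, rel=0.01)

    def test_zero_mu_pure_confocal_recovers_near_zero(self, laser):
        vol = make_profile_volume(laser, 0.0)
        fit = recon.fit_attenuation(vol, max_depth_um=400.0)
        assert fit.mu_median_mm <= 0.01

    @pytest.mark.parametrize("mu", [1.0, 2.0, 4.0, 8.0])
    def test_bias_under_noise_below_five_percent(self, laser, mu, rng):
        """1% additive noise: median recovered coefficient within 5%."""
        estimates = []
        for _ in range(30):
            vol = make_profile_volume(laser, mu, noise_sd=0.01, rng=rng)
            fit = recon.fit_attenuation(vol, max_depth_um=400.0)
            estimates.append(fit.mu_median_mm)
        assert np.mean(estimates) == pytest.approx(mu, rel=0.05)

    def test_all_zero_aline_flagged_not_raised(self, laser):
        vol = make_profile_volume(laser, 2.0)
        vol.intensity[:, 0, 0] = 0.0
        fit = recon.fit_attenuation(vol, max_depth_um=400.0)
        assert not fit.valid[0, 0]
        assert fit.mu_median_mm == pytest.approx(2.0, rel=0.01)

    def test_too_few_axial_samples_rejected(self, laser):
        vol = make_profile_volume(laser, 2.0)
        with pytest.raises(ValueError):
            recon.fit_attenuation(vol, tissue_surface_z_um=1600.0)


class TestCompensation:
    def test_exact_model_becomes_depth_constant(self, laser):
        vol = make_profile_volume(laser, 2.0)
        fit = recon.fit_attenuation(vol, max_depth_um=400.0)
        comp = recon.compensate_depth(vol, fit)
        z = vol.depth_axis_um
        band = (z >= 120.0) & (z <= 480.0)
        prof = comp.intensity[band, 1, 1]
        assert prof.std() / prof.mean() < 0.01

    def test_identity_when_mu_zero_and_flat_confocal(self, laser):
        vol = make_profile_volume(laser, 0.0, z_r=1e9)
        fit = AttenuationFit(
            mu_mm=np.zeros((3, 3)),
            i0=np.ones((3, 3)),
            valid=np.ones((3, 3), dtype=bool),
            residual_rms=np.zeros((3, 3)),
            z_f_um=100.0,
            z_r_um=1e9,
            surface_z_um=100.0,
        )
        comp = recon.compensate_depth(vol, fit)
        assert np.allclose(comp.intensity, vol.intensity, rtol=1e-9)

    def test_never_negative(self, laser, rng):
        vol = make_profile_volume(laser, 3.0, noise_sd=0.02, rng=rng)
        fit = recon.fit_attenuation(vol, max_depth_um=400.0)
        comp = recon.compensate_depth(vol, fit)
        assert (comp.intensity >= 0).all()

    def test_refit_after_compensation_near_zero(self, laser):
        """Idempotence: fitting the compensated volume returns mu ~ 0."""
        vol = make_profile_volume(laser, 2.0)
        fit = recon.fit_attenuation(vol, max_depth_um=400.0)
        comp = recon.compensate_depth(vol, fit)
        refit = recon.fit_attenuation(comp, max_depth_um=400.0)
        assert refit.mu_median_mm <= 0.05


class TestFocalStackFusion:
    def _vol(self, data, focal, laser):
        return IntensityVolume(
            intensity=data,
            voxel_size_um=(laser.depth_bin_um(), 20.0, 20.0),
            focal_depth_um=focal,
        )

    def test_single_volume_identity(self, laser):
        v = self._vol(np.random.default_rng(0).random((64, 3, 3)), 100.0, laser)
        assert recon.fuse_focal_stack([v]) is v

    def test_partition_of_unity_constant_input(self, laser):
        vols = [
            self._vol(np.full((64, 3, 3), 2.5), 100.0 + 16.0 * k, laser)
            for k in range(4)
        ]
        fused = recon.fuse_focal_stack(vols)
        assert np.allclose(fused.intensity, 2.5, atol=1e-12)

    def test_in_focus_weight_dominates(self):
        """At each focal plane the in-focus member's weight exceeds 0.9
        (HWHM of the Gaussian weight = half the plane spacing)."""
        focal = np.array([100.0, 116.0])
        w = recon.fusion_weights(focal, np.array(focal))
        assert w[0, 0] > 0.9 and w[1, 1] > 0.9
        assert np.allclose(w.sum(axis=0), 1.0)

    def test_unsorted_stack_rejected(self, laser):
        v1 = self._vol(np.zeros((64, 3, 3)), 132.0, laser)
        v2 = self._vol(np.zeros((64, 3, 3)), 100.0, laser)
        with pytest.raises(ValueError):
            recon.fuse_focal_stack([v1, v2])


def test_measured_axial_psf_fwhm(laser):
    """PSF width from a simulated mirror: the sigma = 20 nm spectral window
    gives ~12 um FWHM in tissue (n = 1.33) on this grid; recorded here
    because the nominal system resolution depends on this convention."""
    n = laser.n_k_samples
    m0 = 60
    spectrum = np.zeros(n, dtype=complex)
    k = laser.k_grid()
    j_center = (2 * np.pi / laser.apod_mu_nm - k[0]) / (k[1] - k[0])
    spectrum[m0] = np.exp(-2j * np.pi * j_center * m0 / n)
    fringe = np.real(np.fft.ifft(spectrum) * n)
    profile = recon.reconstruct_aline(fringe, np.zeros(n), laser)
    amp = np.sqrt(profile)
    half = amp.max() / 2.0
    above = np.nonzero(amp >= half)[0]
    fwhm_bins = above[-1] - above[0] + 1
    fwhm_um = fwhm_bins * laser.depth_bin_um()
    assert 6.0 <= fwhm_um <= 20.0
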