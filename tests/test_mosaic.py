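"""Stage model, phase correlation, blending partition of unity, stitching
geometry and 3-D assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from serialoct import mosaic
from serialoct._exceptions import DegenerateInputError
from serialoct.mosaic import MosaicGrid, StageModel
from serialoct.optics import TileSpec
from serialoct.recon import IntensityVolume


class TestPhaseCorrelation:
    def test_identical_images_zero_shift(self, rng):
        img = rng.standard_normal((48, 48))
        shift, peak = mosaic.phase_correlation(img, img)
        assert np.array_equal(shift, [0.0, 0.0])
        assert peak == pytest.approx(1.0, abs=1e-9)

    def test_planted_circular_shift_exact(self, rng):
        img = rng.standard_normal((64, 64))
        shifted = np.roll(img, (7, -3), axis=(0, 1))
        shift, _ = mosaic.phase_correlation(img, shifted)
        assert np.array_equal(shift, [7.0, -3.0])

    def test_randomized_planted_shifts_exact(self):
        """50 random planted shifts within a third of the image are all
        recovered exactly."""
        for seed in range(50):
            r = np.random.default_rng(seed)
            img = r.standard_normal((60, 60))
            dy, dx = int(r.integers(-20, 21)), int(r.integers(-20, 21))
            shift, _ = mosaic.phase_correlation(img, np.roll(img, (dy, dx), axis=(0, 1)))
            assert np.array_equal(shift, [dy, dx]), (seed, dy, dx, shift)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            mosaic.phase_correlation(np.ones((16, 16)), np.ones((16, 16)))


class TestCalibrateStage:
    def test_orthogonal_unit_stage(self):
        pm = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [50.0, 50.0]])
        model = mosaic.calibrate_stage(pm, 2.0 * pm)
        assert np.allclose(model.A, 2.0 * np.eye(2), atol=1e-9)
        assert np.allclose(model.b, 0.0, atol=1e-9)

    def test_sheared_stage_recovered_exactly(self, rng):
        """1 degree inter-axis shear, noiseless: elementwise 1e-9 recovery."""
        shear = np.tan(np.deg2rad(1.0))
        A = np.array([[1.0, shear], [0.0, 1.0]])
        b = np.array([12.0, -7.0])
        pm = rng.uniform(-5000, 5000, (12, 2))
        model = mosaic.calibrate_stage(pm, pm @ A.T + b)
        assert np.abs(model.A - A).max() < 1e-9
        assert np.abs(model.b - b).max() < 1e-6

    def test_noisy_recovery_monte_carlo(self):
        """0.5 um measurement noise: A recovered within 1e-3 relative,
        averaged over 100 trials."""
        A = np.array([[1.002, 0.017], [-0.004, 0.998]])
        errs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            pm = r.uniform(-20000, 20000, (20, 2))
            p = pm @ A.T + r.normal(0.0, 0.5, (20, 2))
            model = mosaic.calibrate_stage(pm, p)
            errs.append(np.abs(model.A - A).max() / np.abs(A).max())
        assert np.mean(errs) < 1e-3

    def test_collinear_inputs_rejected(self):
        pm = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(DegenerateInputError):
            mosaic.calibrate_stage(pm, pm)

    def test_round_trip_through_inverse(self, rng):
        model = StageModel(np.array([[1.01, 0.02], [0.0, 0.99]]), np.array([3.0, 4.0]))
        pm = rng.uniform(-1000, 1000, (10, 2))
        back = mosaic.cartesian_to_microsteps(model, mosaic.microsteps_to_cartesian(model, pm))
        assert np.allclose(back, pm, atol=1e-9)


class TestBlendWeights:
    def test_single_tile_weight_one(self):
        grid = MosaicGrid((0.0, 0.0), (25, 25), 20.0)
        w = mosaic.blend_weights([(0.0, 0.0, 500.0, 500.0)], grid)
        assert np.allclose(w[0], 1.0)

    def test_two_tile_overlap_partition_and_monotone(self):
        grid = MosaicGrid((0.0, 0.0), (45, 25), 20.0)
        w = mosaic.blend_weights(
            [(0.0, 0.0, 500.0, 500.0), (400.0, 0.0, 900.0, 500.0)], grid
        )
        total = w.sum(axis=0)
        covered = total > 0
        assert np.abs(total[covered] - 1.0).max() < 1e-6
        overlap_cols = slice(20, 25)
        profile = w[0][overlap_cols, 12]
        assert (np.diff(profile) <= 1e-12).all()  # fades across the overlap

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(0, 600), st.floats(0, 600)), min_size=1, max_size=5))
    def test_partition_of_unity_random_layouts(self, corners):
        grid = MosaicGrid((0.0, 0.0), (30, 30), 40.0)
        footprints = [(x, y, x + 500.0, y + 500.0) for x, y in corners]
        w = mosaic.blend_weights(footprints, grid)
        total = w.sum(axis=0)
        covered = total > 0
        assert np.abs(total[covered] - 1.0).max() < 1e-6
        assert (w >= 0).all()


def make_tile(data, origin, px=20.0, dz=10.0, surface=0.0):
    return IntensityVolume(
        intensity=data,
        voxel_size_um=(dz, px, px),
        cartesian_origin_um=origin,
        surface_z_um=surface,
    )


class TestStitchSlice:
    def test_grid_span_matches_stride_arithmetic(self):
        """3x3 grid of 0.5 mm tiles at 20% overlap spans 1.3 mm."""
        ts = TileSpec()
        tiles = []
        for i in range(3):
            for j in range(3):
                tiles.append(
                    make_tile(np.ones((8, 24, 24)), (i * ts.stride_um, j * ts.stride_um),
                              px=ts.pixel_um)
                )
        sm = mosaic.stitch_slice(tiles)
        span_x = sm.volume.shape[1] * sm.pixel_um
        assert span_x == pytest.approx(1300.0, abs=ts.pixel_um)

    def test_constant_tiles_give_constant_mosaic(self):
        ts = TileSpec()
        tiles = [
            make_tile(np.full((6, 24, 24), 3.25), (i * ts.stride_um, 0.0), px=ts.pixel_um)
            for i in range(3)
        ]
        sm = mosaic.stitch_slice(tiles)
        covered = sm.weights.sum(axis=0) > 0
        assert np.abs(sm.volume[:, covered] - 3.25).max() < 1e-6

    def test_reassembly_of_cut_tiles_matches_original(self, rng):
        """Tiles cut from one synthetic slice restitch to the original."""
        from scipy import ndimage

        px = 20.0
        field = ndimage.gaussian_filter(rng.standard_normal((70, 50)), 2.0)
        slice_img = np.tile(field[None], (4, 1, 1))
        tiles = []
        for i0 in (0, 20, 40):
            tiles.append(make_tile(slice_img[:, i0:i0 + 30, :].copy(), (i0 * px, 0.0), px=px))
        sm = mosaic.stitch_slice(tiles)
        covered = sm.weights.sum(axis=0) > 0
        # interior pixels (tile centres align with mosaic centres here)
        assert sm.volume.shape[1:] == (70, 50)
        err = np.abs(sm.volume[0][covered] - field[covered])
        assert err.max() < 1e-6

    def test_aip_of_ones_is_one(self):
        tiles = [make_tile(np.ones((10, 24, 24)), (0.0, 0.0))]
        sm = mosaic.stitch_slice(tiles, aip_depth_um=50.0)
        assert np.allclose(sm.aip, 1.0)

    def test_disjoint_tiles_warn_of_gaps(self):
        tiles = [
            make_tile(np.ones((4, 10, 10)), (0.0, 0.0)),
            make_tile(np.ones((4, 10, 10)), (1000.0, 0.0)),
        ]
        with pytest.warns(UserWarning):
            mosaic.stitch_slice(tiles)

    def test_translation_equivariance(self, rng):
        """Shifting all tile positions by one pixel shifts the mosaic."""
        px = 20.0
        data = rng.random((4, 30, 30))
        t0 = [make_tile(data, (0.0, 0.0), px=px)]
        t1 = [make_tile(data, (px, 0.0), px=px)]
        m0 = mosaic.stitch_slice(t0)
        m1 = mosaic.stitch_slice(t1)
        assert np.allclose(m0.volume, m1.volume)
        assert m1.origin_um[0] - m0.origin_um[0] == pytest.approx(px)


class TestAssembleBrain:
    def _mosaic(self, volume, z_um, px=25.0, dz=25.0, surface=0.0):
        return mosaic.SliceMosaic(
            volume=volume,
            aip=volume.mean(axis=0),
            weights=np.ones((1,) + volume.shape[1:]),
            origin_um=(0.0, 0.0),
            pixel_um=px,
            dz_um=dz,
            z_um=z_um,
            surface_z_um=surface,
        )

    def test_single_slice_resampled_copy(self, rng):
        vol = rng.random((8, 12, 12))
        brain = mosaic.assemble_brain([self._mosaic(vol, 0.0)], voxel_um=25.0)
        assert brain.intensity.shape == (12, 12, 8)
        assert np.allclose(brain.intensity, np.transpose(vol, (1, 2, 0)), atol=1e-9)

    def test_cut_and_reassemble_correlation(self, rng):
        """A synthetic block cut into 200 um slices with 100 um overlap
        reassembles to the original with correlation >= 0.99."""
        from scipy import ndimage

        truth = ndimage.gaussian_filter(rng.standard_normal((24, 24, 40)), 2.0)
        dz = 10.0  # block z spacing 10 um => 400 um deep
        slices = []
        for z0 in (0.0, 200.0):
            b0 = int(z0 / dz)
            sub = truth[:, :, b0:b0 + 30]  # 300 um imaged depth
            slices.append(self._mosaic(np.transpose(sub, (2, 0, 1)), z0, px=10.0, dz=dz))
        brain = mosaic.assemble_brain(slices, voxel_um=10.0)
        nz = brain.intensity.shape[2]
        r = np.corrcoef(
            brain.intensity.ravel(), truth[:, :, :nz].ravel()
        )[0, 1]
        assert r >= 0.99

    def test_slab_weights_partition_of_unity(self):
        z = np.linspace(0.0, 500.0, 101)
        w = mosaic.slab_weights([(0.0, 300.0), (200.0, 500.0)], z)
        total = w.sum(axis=0)
        covered = total > 0
        assert np.abs(total[covered] - 1.0).max() < 1e-6

    def test_gap_between_slices_warns(self, rng):
        vol = rng.random((4, 6, 6))
        s1 = self._mosaic(vol, 0.0, dz=10.0)
        s2 = self._mosaic(vol, 500.0, dz=10.0)
        with pytest.warns(UserWarning):
            mosaic.assemble_brain([s1, s2], voxel_um=25.0, usable_depth_um=40.0)


class TestPolygonToTiles:
    def test_polygon_inside_one_tile(self):
        tiles = mosaic.polygon_to_tiles(
            np.array([[10.0, 10.0], [200.0, 20.0], [100.0, 300.0]])
        )
        assert len(tiles) == 1

    def test_rectangle_1300_by_500(self):
        ts = TileSpec()
        poly = np.array([[0, 0], [1300.0, 0], [1300.0, 500.0], [0, 500.0]])
        tiles = mosaic.polygon_to_tiles(poly, ts)
        xs = sorted(set(t[0] for t in tiles))
        ys = sorted(set(t[1] for t in tiles))
        assert len(xs) == 3 and len(ys) == 1

    def test_every_vertex_covered(self, rng):
        ts = TileSpec()
        for _ in range(10):
            pts = rng.uniform(0, 2500.0, (6, 2))
            hull_order = np.argsort(np.arctan2(*(pts - pts.mean(0)).T[::-1]))
            poly = pts[hull_order]
            try:
                tiles = mosaic.polygon_to_tiles(poly, ts)
            except ValueError:
                continue  # occasionally non-simple; not the property under test
            assert mosaic.polygon_vertices_covered(poly, tiles, ts)

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [100.0, 100.0], [100.0, 0], [0, 100.0]])
        with pytest.raises(ValueError):
            mosaic.polygon_to_tiles(bowtie)
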