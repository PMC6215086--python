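"""Template relocation, ROI overlays, affine label transport, atlas
fractions and per-ROI metric averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from serialoct import mapping
from serialoct._exceptions import DataError, DegenerateInputError
from serialoct.mapping import AffineTransform
from serialoct.roiselect import ROISpec


@pytest.fixture()
def textured_image(rng):
    return ndimage.gaussian_filter(rng.standard_normal((120, 140)), 1.5)


class TestMatchTemplate:
    def test_exact_crop_scores_one_at_origin(self, textured_image):
        crop = textured_image[30:60, 50:90]
        pos, score = mapping.match_template(textured_image, crop)
        assert pos == (30, 50)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_affine_intensity_invariance(self, textured_image):
        crop = 2.5 * textured_image[30:60, 50:90] + 7.0
        pos, score = mapping.match_template(textured_image, crop)
        assert pos == (30, 50)
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_one_pixel(self):
        """Planted crops + 5% noise relocated within 1 px over 50 seeds."""
        for seed in range(50):
            r = np.random.default_rng(seed)
            img = ndimage.gaussian_filter(r.standard_normal((100, 100)), 1.5)
            i0, j0 = int(r.integers(10, 60)), int(r.integers(10, 60))
            crop = img[i0:i0 + 30, j0:j0 + 30].copy()
            crop = crop + 0.05 * np.ptp(crop) * r.standard_normal(crop.shape)
            pos, _ = mapping.match_template(img, crop)
            assert abs(pos[0] - i0) <= 1 and abs(pos[1] - j0) <= 1, seed

    def test_search_window_restricts_and_recovers(self, textured_image):
        crop = textured_image[30:60, 50:90]
        pos, score = mapping.match_template(
            textured_image, crop, search_center_px=(28, 52), search_radius_px=10
        )
        assert pos == (30, 50)

    def test_constant_template_rejected(self, textured_image):
        with pytest.raises(DegenerateInputError):
            mapping.match_template(textured_image, np.ones((10, 10)))

    def test_agrees_with_brute_force_loop(self, rng):
        """NCC argmax equals an explicit O(N*M) correlation loop."""
        img = rng.standard_normal((40, 40))
        tmpl = img[12:20, 25:33] + 0.0
        pos, _ = mapping.match_template(img, tmpl)
        best, best_val = None, -np.inf
        th, tw = tmpl.shape
        tz = (tmpl - tmpl.mean()) / tmpl.std()
        for i in range(40 - th + 1):
            for j in range(40 - tw + 1):
                w = img[i:i + th, j:j + tw]
                if w.std() == 0:
                    continue
                val = ((w - w.mean()) / w.std() * tz).mean()
                if val > best_val:
                    best, best_val = (i, j), val
        assert pos == best


def roi(center, label, fov_mm=0.5, slice_index=0, ocm=100.0):
    return ROISpec(center_um=center, fov_mm=fov_mm, slice_index=slice_index,
                   ocm_thickness_um=ocm, label=label)


class TestBuildOverlay:
    def test_no_rois_all_zero(self):
        ov = mapping.build_overlay([], (20, 20, 10), 25.0)
        assert (ov.labels == 0).all()

    def test_block_size_matches_fov(self):
        ov = mapping.build_overlay([roi((500.0, 500.0), 1)], (40, 40, 20), 25.0)
        sel = np.argwhere(ov.labels == 1)
        extent_x = sel[:, 0].max() - sel[:, 0].min() + 1
        extent_y = sel[:, 1].max() - sel[:, 1].min() + 1
        assert extent_x == 20 and extent_y == 20  # 500 um / 25 um

    def test_distinct_labels_count(self):
        rois = [roi((300.0, 300.0), 1), roi((800.0, 800.0), 2), roi((300.0, 800.0), 3)]
        ov = mapping.build_overlay(rois, (48, 48, 10), 25.0)
        assert set(np.unique(ov.labels)) == {0, 1, 2, 3}

    def test_collision_last_writer_wins(self):
        rois = [roi((500.0, 500.0), 1), roi((520.0, 520.0), 2)]
        ov = mapping.build_overlay(rois, (48, 48, 10), 25.0)
        centre = ov.labels[20, 20, 2]
        assert centre == 2


class TestApplyAffine:
    def _overlay(self):
        rois = [roi((400.0, 400.0), 1, fov_mm=0.3)]
        return mapping.build_overlay(rois, (32, 32, 16), 25.0)

    def test_identity_unchanged(self):
        ov = self._overlay()
        out = mapping.apply_affine(ov, [AffineTransform(np.eye(4))])
        assert np.array_equal(out.labels, ov.labels)

    def test_one_voxel_translation(self):
        ov = self._overlay()
        t = np.eye(4)
        t[0, 3] = 25.0
        out = mapping.apply_affine(ov, [AffineTransform(t)])
        assert np.array_equal(out.labels[1:], ov.labels[:-1])

    def test_round_trip_dice(self):
        ov = self._overlay()
        t = np.eye(4)
        t[:3, 3] = [13.0, -8.0, 6.0]
        t[0, 1] = 0.05
        fwd = AffineTransform(t)
        inv = AffineTransform(np.linalg.inv(t))
        back = mapping.apply_affine(ov, [fwd, inv])
        a = ov.labels == 1
        b = back.labels == 1
        dice = 2.0 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.95

    def test_no_new_labels_invented(self, rng):
        ov = self._overlay()
        t = np.eye(4)
        t[:3, :3] += rng.normal(0, 0.02, (3, 3))
        t[:3, 3] = rng.normal(0, 30.0, 3)
        out = mapping.apply_affine(ov, [AffineTransform(t)])
        assert set(np.unique(out.labels)) <= set(np.unique(ov.labels))

    def test_singular_matrix_rejected(self):
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(ValueError):
            AffineTransform(m)


class TestStructureFractions:
    def _overlay_on(self, shape, rois):
        return mapping.build_overlay(rois, shape, 25.0)

    def test_block_inside_single_label(self):
        atlas = np.full((48, 48, 10), 5, dtype=np.int16)
        ov = self._overlay_on((48, 48, 10), [roi((500.0, 500.0), 1)])
        frac = mapping.structure_fractions(ov, atlas, fiber_labels={5})
        row = frac[(frac.roi_label == 1) & (frac.atlas_label == 5)].iloc[0]
        assert row.fraction == 1.0 and bool(row.fiber_tract)
        frac2 = mapping.structure_fractions(ov, atlas, fiber_labels={9})
        assert not frac2.fiber_tract.any()

    def test_even_straddle_half_half(self):
        atlas = np.zeros((48, 48, 10), dtype=np.int16)
        atlas[:24] = 1
        atlas[24:] = 2
        ov = self._overlay_on((48, 48, 10), [roi((600.0, 600.0), 1)])
        frac = mapping.structure_fractions(ov, atlas, fiber_labels=set())
        by_label = frac.set_index("atlas_label").fraction
        assert by_label[1] == pytest.approx(0.5, abs=0.06)
        assert by_label[2] == pytest.approx(0.5, abs=0.06)

    def test_fractions_sum_to_one(self, rng):
        atlas = rng.integers(0, 4, (48, 48, 10)).astype(np.int16)
        rois = [roi((400.0, 400.0), 1), roi((800.0, 700.0), 2)]
        ov = self._overlay_on((48, 48, 10), rois)
        frac = mapping.structure_fractions(ov, atlas, fiber_labels={3})
        for _, grp in frac.groupby("roi_label"):
            assert grp.fraction.sum() == pytest.approx(1.0, abs=1e-6)

    def test_grid_mismatch_rejected(self):
        ov = self._overlay_on((48, 48, 10), [roi((500.0, 500.0), 1)])
        with pytest.raises(DataError):
            mapping.structure_fractions(ov, np.zeros((10, 10, 10)), set())


class TestROIMetricAverage:
    def test_constant_metric(self):
        ov = mapping.build_overlay([roi((500.0, 500.0), 1)], (48, 48, 10), 25.0)
        means = mapping.roi_metric_average(ov, np.full((48, 48, 10), 0.37))
        assert means[1] == pytest.approx(0.37)

    def test_half_and_half_block(self):
        ov = mapping.build_overlay([roi((600.0, 600.0), 1)], (48, 48, 10), 25.0)
        metric = np.where(np.arange(48)[:, None, None] < 24, 0.2, 0.6) * np.ones((48, 48, 10))
        means = mapping.roi_metric_average(ov, metric)
        assert means[1] == pytest.approx(0.4, abs=0.03)

    def test_matches_brute_force_loop(self, rng):
        rois = [roi((400.0, 400.0), 1), roi((800.0, 700.0), 2)]
        ov = mapping.build_overlay(rois, (48, 48, 10), 25.0)
        metric = rng.random((48, 48, 10))
        metric[0, 0, 0] = np.nan
        means = mapping.roi_metric_average(ov, metric)
        for lab in (1, 2):
            acc = [
                metric[i, j, k]
                for i in range(48) for j in range(48) for k in range(10)
                if ov.labels[i, j, k] == lab and np.isfinite(metric[i, j, k])
            ]
            assert means[lab] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_missing_roi_reports_nan(self):
        ov = mapping.build_overlay([roi((500.0, 500.0), 1)], (48, 48, 10), 25.0)
        ov.roi_table = pd.concat(
            [ov.roi_table, pd.DataFrame([{"label": 9, "center_x_um": 0.0,
                                          "center_y_um": 0.0, "slice_index": 0,
                                          "fov_mm": 0.5, "mode": "auto"}])],
            ignore_index=True,
        )
        means = mapping.roi_metric_average(ov, np.ones((48, 48, 10)))
        assert np.isnan(means[9])
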