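"""Planar metrics: ROI means, H/M ratio, global washout rate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibgtools import (
    PlanarScan,
    RoiSpec,
    auto_heart_roi,
    hm_ratio,
    mean_counts,
    mediastinum_box_roi,
    washout_rate,
)

PX = 2.5  # mm; 1,200 mm^2 == 192 pixels


def scan(counts, timepoint="early_15min", px=PX):
    return PlanarScan(counts=np.asarray(counts, dtype=float),
                      pixel_size_mm=(px, px), timepoint=timepoint)


def med_mask(shape, corner=(0, 0)):
    """A 192-pixel mediastinal mask (exactly 1,200 mm^2 at 2.5 mm pixels)."""
    m = np.zeros(shape, dtype=bool)
    r, c = corner
    m[r:r + 12, c:c + 16] = True
    assert m.sum() == 192
    return m


class TestMeanCounts:
    def test_uniform_image_any_mask(self):
        s = scan(np.full((16, 16), 7.0))
        mask = np.zeros((16, 16), dtype=bool)
        mask[3, 4] = mask[10, 2] = True
        assert mean_counts(s, RoiSpec(mask=mask, label="heart")) == 7.0

    def test_two_pixel_mean(self):
        img = np.zeros((4, 4))
        img[0, 0], img[1, 1] = 10.0, 30.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert mean_counts(scan(img), RoiSpec(mask=mask, label="heart")) == 20.0

    def test_matches_elementwise_loop_oracle(self, rng):
        img = rng.uniform(0, 100, size=(16, 16))
        mask = rng.random((16, 16)) < 0.4
        mask[0, 0] = True  # nonempty
        total, n = 0.0, 0
        for i in range(16):
            for j in range(16):
                if mask[i, j]:
                    total += img[i, j]
                    n += 1
        assert mean_counts(scan(img), RoiSpec(mask=mask, label="heart")) == pytest.approx(total / n)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            RoiSpec(mask=np.zeros((4, 4), dtype=bool), label="heart")

    def test_incongruent_mask_rejected(self):
        s = scan(np.ones((8, 8)))
        with pytest.raises(ValueError):
            mean_counts(s, RoiSpec(mask=np.ones((4, 4), dtype=bool), label="heart"))


class TestHmRatio:
    def test_simple_ratio(self):
        img = np.zeros((32, 32))
        img[20:28, 20:28] = 240.0
        img[:12, :16] = 80.0
        heart = RoiSpec(mask=img == 240.0, label="heart")
        med = RoiSpec(mask=med_mask((32, 32)), label="mediastinum")
        assert hm_ratio(scan(img), heart, med) == pytest.approx(3.0)

    def test_identical_rois_give_unity(self):
        img = np.random.default_rng(0).uniform(1, 5, (32, 32))
        mask = med_mask((32, 32))
        heart = RoiSpec(mask=mask, label="heart")
        med = RoiSpec(mask=mask, label="mediastinum")
        assert hm_ratio(scan(img), heart, med) == pytest.approx(1.0)

    def test_projected_phantom_recovers_constructed_ratio(self):
        """A slab-heart phantom built so projected heart pixels are exactly
        2.9x the mediastinal band (the study's printed pre-PVI mean)."""
        from mibgtools import LvAxis, LvVolume, PhantomSpec, planar_project

        ratio = 2.9
        depth, v = 20, 50.0
        counts = np.zeros((32, 48, 48))
        counts[5:5 + depth, 20:32, 5:20] = v
        vol = LvVolume(
            counts=counts, voxel_size_mm=(PX, PX, PX),
            axis=LvAxis(base=(16, 26, 5), apex=(16, 26, 19)),
            timepoint="late_4h",
        )
        spec = PhantomSpec(
            grid_shape=(32, 48, 48), voxel_size_mm=(PX, PX, PX),
            lv_center=(16.0, 26.0, 5.0), lv_radii_mm=(25.0, 25.0, 36.0),
            mediastinum_activity=depth * v / (ratio * 32),
        )
        s = planar_project(vol, background_model=spec)
        hmask = np.zeros_like(s.counts, dtype=bool)
        hmask[22:30, 7:18] = True
        heart = RoiSpec(mask=hmask, label="heart")
        med = mediastinum_box_roi(s, corner=(16, 30))
        assert np.all(s.counts[med.mask] > 0)
        assert hm_ratio(s, heart, med) == pytest.approx(ratio, abs=1e-6)

    def test_zero_mediastinum_is_an_error(self):
        img = np.zeros((32, 32))
        img[20:24, 20:24] = 10.0
        heart = RoiSpec(mask=img > 0, label="heart")
        med = RoiSpec(mask=med_mask((32, 32)), label="mediastinum")
        with pytest.raises(ValueError, match="H/M undefined"):
            hm_ratio(scan(img), heart, med)

    def test_mediastinal_area_outside_band_rejected(self):
        img = np.ones((32, 32))
        heart = RoiSpec(mask=img > 0, label="heart")
        small = np.zeros((32, 32), dtype=bool)
        small[0, 0:10] = True  # 62.5 mm^2, far from 1,200
        with pytest.raises(ValueError, match="mediastinal ROI area"):
            hm_ratio(scan(img), heart, RoiSpec(mask=small, label="mediastinum"))


def _wr_fixture(he, me, hl, ml):
    early_img = np.zeros((32, 32))
    late_img = np.zeros((32, 32))
    hmask = np.zeros((32, 32), dtype=bool)
    hmask[20:28, 20:28] = True
    mmask = med_mask((32, 32))
    early_img[hmask], early_img[mmask] = he, me
    late_img[hmask], late_img[mmask] = hl, ml
    return (
        scan(early_img, "early_15min"),
        scan(late_img, "late_4h"),
        RoiSpec(mask=hmask, label="heart"),
        RoiSpec(mask=mmask, label="mediastinum"),
    )


class TestWashoutRate:
    def test_default_background_subtracted_form(self):
        e, l, h, m = _wr_fixture(200, 50, 125, 50)
        assert washout_rate(e, l, h, m) == pytest.approx(50.0)

    def test_identical_scans_give_zero(self):
        e, _, h, m = _wr_fixture(200, 50, 125, 50)
        twin = PlanarScan(counts=e.counts.copy(), pixel_size_mm=e.pixel_size_mm,
                          timepoint="late_4h")
        assert washout_rate(e, twin, h, m) == pytest.approx(0.0)

    def test_decay_correction_matches_closed_form(self):
        e, l, h, m = _wr_fixture(200, 50, 125, 50)
        factor = 2.0 ** ((4.0 - 0.25) / 13.2232)
        expected = 100.0 * (150.0 - factor * 75.0) / 150.0
        got = washout_rate(e, l, h, m, decay_correct=True)
        assert got == pytest.approx(expected, abs=1e-12)
        assert factor == pytest.approx(1.217, abs=5e-4)

    def test_nonpositive_denominator_is_an_error(self):
        e, l, h, m = _wr_fixture(50, 50, 40, 30)
        with pytest.raises(ValueError, match="washout rate undefined"):
            washout_rate(e, l, h, m)

    @given(factor=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance_of_hm_and_wr(self, factor):
        e, l, h, m = _wr_fixture(200, 50, 125, 50)
        e2 = PlanarScan(counts=e.counts * factor, pixel_size_mm=e.pixel_size_mm,
                        timepoint=e.timepoint)
        l2 = PlanarScan(counts=l.counts * factor, pixel_size_mm=l.pixel_size_mm,
                        timepoint=l.timepoint)
        assert hm_ratio(e2, h, m) == pytest.approx(hm_ratio(e, h, m))
        assert washout_rate(e2, l2, h, m) == pytest.approx(washout_rate(e, l, h, m))

    def test_sign_antisymmetry_under_time_swap_without_decay_correction(self):
        e, l, h, m = _wr_fixture(200, 50, 125, 50)
        fwd = washout_rate(e, l, h, m)
        e_as_late = PlanarScan(counts=e.counts, pixel_size_mm=e.pixel_size_mm,
                               timepoint="late_4h")
        l_as_early = PlanarScan(counts=l.counts, pixel_size_mm=l.pixel_size_mm,
                                timepoint="early_15min")
        rev = washout_rate(l_as_early, e_as_late, h, m)
        assert fwd > 0 > rev


class TestConvenienceRois:
    def test_auto_heart_roi_finds_the_hot_component(self, uniform_study):
        roi = auto_heart_roi(uniform_study.planar_late)
        proj = (uniform_study.segment_labels > 0).sum(axis=0) > 0
        # the detected component must lie within the projected LV footprint
        assert roi.mask.sum() > 0
        assert np.all(proj[roi.mask])

    def test_mediastinum_box_area_tiles_1200mm2(self):
        s = scan(np.ones((48, 48)))
        roi = mediastinum_box_roi(s, corner=(2, 2))
        assert roi.mask.sum() * s.pixel_area_mm2 == pytest.approx(1200.0)

    def test_box_outside_image_rejected(self):
        s = scan(np.ones((8, 8)))
        with pytest.raises(ValueError):
            mediastinum_box_roi(s, corner=(6, 6))
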