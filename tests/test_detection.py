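"""Lane/band auto-detection and the manual-edit vocabulary."""

import numpy as np
import pytest

from gelkit import detection as det
from gelkit import synthetic as syn
from gelkit.image import GelImage


def noiseless(lanes, w=800, h=340, bg=15.0, gradient=0.0):
    spec = syn.GelSpec(width_px=w, height_px=h, lanes=lanes,
                       background_level=bg, background_gradient=gradient,
                       noise_sigma=0.0)
    return syn.generate_gel(spec)


class TestColumnProfile:
    def test_uniform_image_gives_zero_profile(self):
        img = GelImage(pixels=np.full((50, 80), 37, dtype=np.uint8))
        prof = det.column_profile(img)
        assert np.allclose(prof.values, 0.0)

    def test_single_lane_support_matches_truth(self):
        img, truth = noiseless([syn.LaneSpec(x_center=100, width=30, bands=[
            syn.BandSpec(y_center=150, peak_intensity=150, sigma=3)])])
        prof = det.column_profile(img)
        support = np.where(prof.values > 0.5 * prof.values.max())[0]
        lo, hi = truth.lanes[0].x_top
        assert abs(support.min() - lo) <= 1
        assert abs(support.max() - (hi - 1)) <= 1

    def test_two_identical_lanes_give_equal_plateaus(self):
        bands = [syn.BandSpec(y_center=150, peak_intensity=150, sigma=3)]
        img, _ = noiseless([
            syn.LaneSpec(x_center=80, width=30, bands=list(bands)),
            syn.LaneSpec(x_center=220, width=30, bands=list(bands))])
        prof = det.column_profile(img)
        left = prof.values[70:90].max()
        right = prof.values[210:230].max()
        assert left == pytest.approx(right, rel=0.02)

    def test_rgb_input_rejected(self):
        img = GelImage(pixels=np.zeros((5, 5, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="grayscale"):
            det.column_profile(img)


class TestDetectLanes:
    def test_blank_image_has_no_lanes(self):
        img = GelImage(pixels=np.full((60, 90), 22, dtype=np.uint8))
        assert len(det.detect_lanes(img)) == 0

    def test_three_lane_recovery_within_2px(self, three_lane_gel):
        img, truth = three_lane_gel
        lanes = det.detect_lanes(img).sorted()
        assert len(lanes) == 3
        for lane, t in zip(lanes, truth.lanes):
            assert abs(lane.x_top[0] - t.x_top[0]) <= 2
            assert abs(lane.x_top[1] - t.x_top[1]) <= 2

    def test_full_width_lane_degenerates_to_whole_image(self):
        img, _ = noiseless([syn.LaneSpec(x_center=50, width=100, bands=[
            syn.BandSpec(y_center=60, peak_intensity=120, sigma=3)])],
            w=100, h=200)
        lanes = det.detect_lanes(img)
        assert len(lanes) == 1
        assert lanes.lanes[0].x_top == (0, 100)


class TestDetectBands:
    def test_flat_lane_has_no_bands(self):
        img = GelImage(pixels=np.full((80, 60), 30, dtype=np.uint8))
        lane = det.Lane(x_top=(10, 50), y_range=(0, 80))
        assert det.detect_bands(img, lane) == []

    def test_four_gaussian_bands_found_exactly(self):
        ys = [60, 120, 180, 240]
        img, _ = noiseless([syn.LaneSpec(x_center=60, width=40, bands=[
            syn.BandSpec(y_center=y, peak_intensity=150, sigma=2) for y in ys])],
            w=120, h=300)
        lane = det.Lane(x_top=(40, 80), y_range=(0, 300))
        bands = det.detect_bands(img, lane)
        assert len(bands) == 4
        for band, y in zip(bands, ys):
            assert abs(band.y_center - y) <= 1
            assert band.y_top < band.y_center < band.y_bottom

    def test_close_peaks_merged_by_separation_rule(self):
        img, _ = noiseless([syn.LaneSpec(x_center=60, width=40, bands=[
            syn.BandSpec(y_center=100, peak_intensity=150, sigma=1),
            syn.BandSpec(y_center=102, peak_intensity=150, sigma=1)])],
            w=120, h=200)
        lane = det.Lane(x_top=(40, 80), y_range=(0, 200))
        bands = det.detect_bands(img, lane, min_separation=3)
        assert len(bands) == 1

    def test_redetection_is_idempotent(self, three_lane_gel):
        img, _ = three_lane_gel
        lanes = det.detect_lanes(img).sorted()
        lane = lanes.lanes[0]
        again = det.detect_bands(img, lane)
        assert [(b.y_top, b.y_center, b.y_bottom) for b in lane.bands] == \
               [(b.y_top, b.y_center, b.y_bottom) for b in again]

    def test_lane_outside_image_rejected(self, three_lane_gel):
        img, _ = three_lane_gel
        lane = det.Lane(x_top=(950, 1100))
        with pytest.raises(ValueError, match="outside"):
            det.detect_bands(img, lane)


class TestLaneSplitMerge:
    def test_split_partitions_interval(self, three_lane_gel):
        img, _ = three_lane_gel
        lanes = det.detect_lanes(img).sorted()
        lane = lanes.lanes[0]
        lo, hi = lane.x_top
        mid = (lo + hi) // 2
        out = det.split_lane(img, lanes, lane.id, mid).sorted()
        assert len(out) == 4
        assert out.lanes[0].x_top == (lo, mid)
        assert out.lanes[1].x_top == (mid, hi)

    def test_split_then_merge_restores_geometry(self, three_lane_gel):
        img, _ = three_lane_gel
        lanes = det.detect_lanes(img).sorted()
        lane = lanes.lanes[1]
        lo, hi = lane.x_top
        split = det.split_lane(img, lanes, lane.id, (lo + hi) // 2).sorted()
        two = [l for l in split if lo <= l.x_top[0] < hi]
        merged = det.merge_lanes(img, split, [l.id for l in two]).sorted()
        assert len(merged) == 3
        assert any(l.x_top == (lo, hi) for l in merged)

    def test_split_at_boundary_rejected(self, three_lane_gel):
        img, _ = three_lane_gel
        lanes = det.detect_lanes(img).sorted()
        lane = lanes.lanes[0]
        with pytest.raises(ValueError):
            det.split_lane(img, lanes, lane.id, lane.x_top[0])

    def test_merge_spans_hull_and_absorbs_gutter(self, three_lane_gel):
        img, _ = three_lane_gel
        lanes = det.detect_lanes(img).sorted()
        a, b = lanes.lanes[0], lanes.lanes[1]
        out = det.merge_lanes(img, lanes, [a.id, b.id]).sorted()
        assert len(out) == 2
        assert out.lanes[0].x_top == (a.x_top[0], b.x_top[1])

    def test_merge_of_single_lane_rejected(self, three_lane_gel):
        img, _ = three_lane_gel
        lanes = det.detect_lanes(img)
        with pytest.raises(ValueError):
            det.merge_lanes(img, lanes, [lanes.lanes[0].id])

    def test_oversplit_lane_recovers_truth_after_merge(self):
        """A double-width region holding two true lanes, split at the valley."""
        bands1 = [syn.BandSpec(y_center=80, peak_intensity=170, sigma=2.5),
                  syn.BandSpec(y_center=200, peak_intensity=170, sigma=2.5)]
        bands2 = [syn.BandSpec(y_center=140, peak_intensity=170, sigma=2.5)]
        img, truth = noiseless([
            syn.LaneSpec(x_center=80, width=36, bands=bands1),
            syn.LaneSpec(x_center=120, width=36, bands=bands2)], w=200, h=260)
        # pretend detection produced one big lane over both
        big = det.Lane(x_top=(62, 138), y_range=(0, 260))
        big.bands = det.detect_bands(img, big)
        lanes = det.LaneSet([big])
        out = det.split_lane(img, lanes, big.id, 100).sorted()
        left, right = out.lanes
        assert sorted(round(b.y_center) for b in left.bands) == [80, 200]
        assert sorted(round(b.y_center) for b in right.bands) == [140]


class TestBandSplitMerge:
    def make_lane(self):
        lane = det.Lane(x_top=(10, 50), y_range=(0, 100))
        band = det.Band(y_top=40, y_center=50, y_bottom=60, lane_id=lane.id)
        lane.bands = [band]
        return lane, band

    def test_split_partitions_with_midpoint_centers(self):
        lane, band = self.make_lane()
        out = det.split_band(lane, band.id, 50)
        assert [(b.y_top, b.y_center, b.y_bottom) for b in out.bands] == \
               [(40, 45, 50), (50, 55, 60)]

    def test_split_then_merge_restores_extent(self):
        lane, band = self.make_lane()
        split = det.split_band(lane, band.id, 50)
        merged = det.merge_bands(split, [b.id for b in split.bands])
        assert len(merged.bands) == 1
        assert (merged.bands[0].y_top, merged.bands[0].y_bottom) == (40, 60)

    def test_merge_equal_density_bands_centers_at_midpoint(self):
        lane = det.Lane(x_top=(10, 50), y_range=(0, 100))
        b1 = det.Band(y_top=40, y_center=44, y_bottom=48, lane_id=lane.id,
                      density=500.0)
        b2 = det.Band(y_top=52, y_center=56, y_bottom=60, lane_id=lane.id,
                      density=500.0)
        lane.bands = [b1, b2]
        out = det.merge_bands(lane, [b1.id, b2.id])
        assert out.bands[0].y_center == pytest.approx(50.0)

    def test_split_outside_extent_rejected(self):
        lane, band = self.make_lane()
        with pytest.raises(ValueError):
            det.split_band(lane, band.id, 70)

    def test_merge_across_lanes_rejected(self):
        lane, band = self.make_lane()
        foreign = det.Band(y_top=70, y_center=75, y_bottom=80, lane_id=99999)
        with pytest.raises(ValueError):
            det.merge_bands(lane, [band.id, foreign.id])


class TestManualEdits:
    def test_add_overlapping_lane_rejected(self, three_lane_gel):
        img, _ = three_lane_gel
        lanes = det.detect_lanes(img).sorted()
        lo, hi = lanes.lanes[0].x_top
        with pytest.raises(ValueError, match="overlap"):
            det.edit_lane(img, lanes, "add", x_top=(lo + 5, hi + 5))

    def test_remove_then_readd_restores_geometry_with_fresh_id(self, three_lane_gel):
        img, _ = three_lane_gel
        lanes = det.detect_lanes(img).sorted()
        lane = lanes.lanes[2]
        removed = det.edit_lane(img, lanes, "remove", lane_id=lane.id)
        assert len(removed) == 2
        readded = det.edit_lane(img, removed, "add", x_top=lane.x_top).sorted()
        new = readded.lanes[2]
        assert new.x_top == lane.x_top and new.id != lane.id

    def test_band_edit_overlap_rejected(self):
        lane = det.Lane(x_top=(10, 50), y_range=(0, 100))
        lane = det.edit_band(lane, "add", y_top=40, y_bottom=60)
        with pytest.raises(ValueError, match="overlap"):
            det.edit_band(lane, "add", y_top=55, y_bottom=70)

    def test_set_tilt_recovers_bands_untilted_detection_misses(self):
        """A strongly tilted lane: untilted tracking loses the deep bands."""
        lanes = [syn.LaneSpec(x_center=60, width=40, tilt=47, bands=[
            syn.BandSpec(y_center=60, peak_intensity=180, sigma=2.5),
            syn.BandSpec(y_center=240, peak_intensity=180, sigma=2.5)])]
        spec = syn.GelSpec(width_px=200, height_px=300, lanes=lanes,
                           background_level=15, noise_sigma=0.0)
        img, truth = syn.generate_gel(spec)
        top_iv = truth.lanes[0].x_top
        untilted = det.Lane(x_top=top_iv, y_range=(0, 300))
        found = det.detect_bands(img, untilted)
        missed = [y for y in (60, 240)
                  if not any(abs(b.y_center - y) < 3 for b in found)]
        assert missed, "untilted tracking should lose the deep band"
        lanes_set = det.LaneSet([untilted])
        tilted = det.edit_lane(img, lanes_set, "set_tilt", lane_id=untilted.id,
                               x_top=top_iv, x_bottom=truth.lanes[0].x_bottom)
        lane = tilted.lanes[0]
        for y in (60, 240):
            assert any(abs(b.y_center - y) <= 1 for b in lane.bands)


def test_laneset_rejects_overlap_on_construction():
    a = det.Lane(x_top=(0, 20))
    b = det.Lane(x_top=(10, 30))
    with pytest.raises(ValueError, match="overlap"):
        det.LaneSet([a, b])
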