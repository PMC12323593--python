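import numpy as np
import pytest

from flaps_phenotyper.detect import (
    SegmentationParams,
    detect_field,
    estimate_background,
    merge_exposures,
    segment_channel,
    signal_background_ratio,
)
from flaps_phenotyper.errors import DegenerateBackgroundError, InputError
from flaps_phenotyper.simulate import SimFieldConfig, simulate_field

from conftest import make_channel, obj_from_mask


def brute_force_components(binary: np.ndarray) -> list[set]:
    """Independent 8-connected component labeling by BFS (test oracle)."""
    h, w = binary.shape
    seen = np.zeros_like(binary, bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.add(y * w + x)
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (
                                0 <= yy < h
                                and 0 <= xx < w
                                and binary[yy, xx]
                                and not seen[yy, xx]
                            ):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(comp)
    return comps


def _disk_raster(shape, disks, level=1000.0, background=100.0):
    """Raster with bright disks at (row, col, radius)."""
    img = np.full(shape, background)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for r, c, rad in disks:
        img[(yy - r) ** 2 + (xx - c) ** 2 <= rad**2] = level
    return img


PARAMS = SegmentationParams(min_area_um2=0.05, max_area_um2=20.0)


class TestSegmentChannel:
    def test_constant_raster_yields_no_objects(self):
        img = make_channel(np.full((64, 64), 100.0))
        assert segment_channel(img, PARAMS, 0.1) == []

    def test_five_disks_match_brute_force_oracle(self):
        disks = [(10, 10, 3), (10, 40, 4), (30, 25, 3), (50, 10, 5), (50, 50, 3)]
        raster = _disk_raster((64, 64), disks)
        objs = segment_channel(make_channel(raster), PARAMS, 0.1)
        assert len(objs) == 5
        expected = brute_force_components(raster > 100.0)
        got = [set(o.pixels.tolist()) for o in objs]
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))

    def test_object_below_min_area_excluded(self):
        # a radius-3 disk has 29 px = 0.29 um^2 at 0.1 um/px
        raster = _disk_raster((64, 64), [(20, 20, 3), (40, 40, 10)])
        params = SegmentationParams(min_area_um2=0.5, max_area_um2=20.0)
        objs = segment_channel(make_channel(raster), params, 0.1)
        assert len(objs) == 1
        assert objs[0].area_um2 > 0.5

    def test_segmentation_is_deterministic(self):
        rng = np.random.default_rng(0)
        raster = np.clip(
            _disk_raster((64, 64), [(20, 20, 4)]) + rng.normal(0, 5, (64, 64)), 0, 4095
        )
        a = segment_channel(make_channel(raster), PARAMS, 0.1)
        b = segment_channel(make_channel(raster), PARAMS, 0.1)
        assert len(a) == len(b)
        for oa, ob in zip(a, b):
            np.testing.assert_array_equal(oa.pixels, ob.pixels)
            assert oa.sbr == ob.sbr

    def test_saturation_flag_set_when_clipped(self):
        raster = _disk_raster((64, 64), [(20, 20, 4)], level=4095.0)
        objs = segment_channel(make_channel(raster), PARAMS, 0.1)
        assert len(objs) == 1 and objs[0].saturated

    def test_otsu_method_also_finds_objects(self):
        raster = _disk_raster((64, 64), [(20, 20, 4)])
        params = SegmentationParams(threshold_method="otsu")
        assert len(segment_channel(make_channel(raster), params, 0.1)) == 1

    def test_noise_free_simulated_dapi_count_matches_truth(self):
        fov, truth = simulate_field(SimFieldConfig(seed=21, shape=(192, 192), n_cells=30))
        objs = segment_channel(fov.dapi, PARAMS, fov.meta.pixel_size_um)
        assert len(objs) == truth.n_cells


class TestSignalBackground:
    def test_uniform_image_gives_unit_ratio(self):
        img = make_channel(np.full((32, 32), 100.0))
        mask = np.zeros((32, 32), bool)
        mask[10:15, 10:15] = True
        assert signal_background_ratio(mask, img, 100.0) == 1.0

    @pytest.mark.parametrize("mean,bg,expected", [(200.0, 100.0, 2.0), (50.0, 100.0, 0.5)])
    def test_ratio_arithmetic(self, mean, bg, expected):
        raster = np.full((32, 32), bg)
        mask = np.zeros((32, 32), bool)
        mask[5:10, 5:10] = True
        raster[mask] = mean
        img = make_channel(raster)
        assert signal_background_ratio(mask, img, bg) == pytest.approx(expected)

    def test_zero_background_rejected(self):
        img = make_channel(np.full((32, 32), 10.0))
        with pytest.raises(DegenerateBackgroundError):
            signal_background_ratio(np.ones((32, 32), bool), img, 0.0)

    def test_background_median_constant(self):
        raster = np.full((32, 32), 100.0)
        mask = np.zeros((32, 32), bool)
        mask[0:5, 0:5] = True
        raster[mask] = 4000.0
        assert estimate_background(make_channel(raster), [mask]) == 100.0

    def test_background_median_by_enumeration(self):
        # 108 background pixels cycling 1..9 -> median 5
        vals = np.tile(np.arange(1.0, 10.0), 12)
        raster = np.concatenate([vals, np.full(36, 4000.0)]).reshape(12, 12)
        mask = raster >= 4000.0
        assert estimate_background(make_channel(raster), [mask]) == 5.0

    def test_all_masked_raises(self):
        img = make_channel(np.full((32, 32), 100.0))
        with pytest.raises(DegenerateBackgroundError):
            estimate_background(img, [np.ones((32, 32), bool)])


def _shifted_disk_obj(center, exposure_ms, saturated=False, shape=(64, 64)):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= 9
    return obj_from_mask(mask, exposure_ms=exposure_ms, saturated=saturated)


class TestMergeExposures:
    def test_lone_dim_object_kept_from_longest_exposure(self):
        objs = {140.0: [_shifted_disk_obj((20, 20), 140.0)], 35.0: [], 10.0: []}
        merged = merge_exposures(objs, 0.1)
        assert len(merged) == 1 and merged[0].exposure_ms == 140.0

    def test_saturated_long_exposure_falls_back(self):
        objs = {
            140.0: [_shifted_disk_obj((20, 20), 140.0, saturated=True)],
            35.0: [_shifted_disk_obj((20, 20), 35.0)],
            10.0: [_shifted_disk_obj((20, 20), 10.0)],
        }
        merged = merge_exposures(objs, 0.1)
        assert len(merged) == 1 and merged[0].exposure_ms == 35.0

    def test_all_saturated_uses_shortest(self):
        objs = {
            140.0: [_shifted_disk_obj((20, 20), 140.0, saturated=True)],
            10.0: [_shifted_disk_obj((20, 20), 10.0, saturated=True)],
        }
        merged = merge_exposures(objs, 0.1)
        assert merged[0].exposure_ms == 10.0

    def test_distant_objects_not_merged(self):
        objs = {
            140.0: [_shifted_disk_obj((10, 10), 140.0)],
            35.0: [_shifted_disk_obj((50, 50), 35.0)],
        }
        assert len(merge_exposures(objs, 0.1)) == 2

    def test_empty_input_empty_output(self):
        assert merge_exposures({10.0: [], 35.0: []}, 0.1) == []

    def test_merged_count_bounded_by_total(self):
        fov, truth = simulate_field(SimFieldConfig(seed=23, shape=(192, 192), n_cells=25))
        det = detect_field(fov, PARAMS)
        per_exp = [
            segment_channel(ch, PARAMS, fov.meta.pixel_size_um) for ch in fov.flaps
        ]
        assert len(det["FLAPS"]) <= sum(len(g) for g in per_exp)


class TestParamValidation:
    def test_bad_connectivity(self):
        with pytest.raises(InputError):
            SegmentationParams(connectivity=6)

    def test_bad_area_bounds(self):
        with pytest.raises(InputError):
            SegmentationParams(min_area_um2=5.0, max_area_um2=1.0)
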