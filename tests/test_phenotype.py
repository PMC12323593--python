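import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flaps_phenotyper.errors import DegenerateObjectError, InputError
from flaps_phenotyper.phenotype import (
    CellRecord,
    Thresholds,
    classify_cell,
    classify_field,
    overlap_fraction,
    quantify_sample,
    reject_background,
    timecourse_summary,
)
from flaps_phenotyper.phenotype import _overlap_pixels
from flaps_phenotyper.detect import SegmentationParams, detect_field
from flaps_phenotyper.io_formats import AcquisitionMeta
from flaps_phenotyper.simulate import SimFieldConfig, simulate_field

from conftest import obj_from_mask

SHAPE = (40, 40)


def _mask(rows, cols):
    m = np.zeros(SHAPE, bool)
    m[rows, cols] = True
    return m


def _block(r0, r1, c0, c1):
    m = np.zeros(SHAPE, bool)
    m[r0:r1, c0:c1] = True
    return m


class TestOverlapFraction:
    def test_identical_masks(self):
        m = _block(5, 10, 5, 10)
        assert overlap_fraction(m, m) == 1.0

    def test_disjoint_masks(self):
        assert overlap_fraction(_block(0, 5, 0, 5), _block(20, 25, 20, 25)) == 0.0

    def test_partial_overlap_by_pixel_count(self):
        ref = _mask([0] * 10, list(range(10)))  # 10 reference pixels
        qry = _mask([0] * 3, [0, 1, 2])  # 3 shared
        assert overlap_fraction(ref, qry) == pytest.approx(0.3)

    def test_empty_reference_rejected(self):
        with pytest.raises(DegenerateObjectError):
            overlap_fraction(np.zeros(SHAPE, bool), _block(0, 5, 0, 5))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**32 - 1))
    def test_mask_and_pixel_paths_agree(self, seed):
        """The mask-based op and the index-based fast path are one function."""
        rng = np.random.default_rng(seed)
        ref = rng.random(SHAPE) < 0.2
        qry = rng.random(SHAPE) < 0.2
        if not ref.any():
            ref[0, 0] = True
        expected = overlap_fraction(ref, qry)
        got = _overlap_pixels(np.flatnonzero(ref), np.flatnonzero(qry))
        assert got == pytest.approx(expected)


class TestClassifyCell:
    def setup_method(self):
        self.dapi = obj_from_mask(_block(10, 20, 10, 20), role="DAPI")

    def _flaps(self, overlap, sbr):
        n = int(round(overlap * 100))
        rows = [10 + k // 10 for k in range(n)]
        cols = [10 + k % 10 for k in range(n)]
        return obj_from_mask(_mask(rows, cols), role="FLAPS", sbr=sbr)

    def test_boundary_overlap_and_sbr_are_inclusive(self):
        rec = classify_cell(self.dapi, [self._flaps(0.30, 1.0)], th=Thresholds())
        assert rec.phenotype == "flaps_cell"

    def test_overlap_just_below_threshold(self):
        rec = classify_cell(self.dapi, [self._flaps(0.29, 5.0)], th=Thresholds())
        assert rec.phenotype == "unstained_cell"

    def test_sbr_below_threshold_fails_even_with_full_overlap(self):
        rec = classify_cell(self.dapi, [self._flaps(1.0, 0.99)], th=Thresholds())
        assert rec.phenotype == "unstained_cell"

    def test_auto_and_flaps_is_cyanobacterium(self):
        auto = obj_from_mask(_block(10, 20, 10, 20), role="AUTO")
        fish = obj_from_mask(_block(10, 20, 10, 20), role="FISH")
        rec = classify_cell(
            self.dapi, [self._flaps(1.0, 5.0)], fish_objs=[fish], auto_objs=[auto]
        )
        assert rec.phenotype == "cyanobacterium"

    def test_flaps_and_fish_is_flaps_fish_cell(self):
        fish = obj_from_mask(_block(10, 20, 10, 20), role="FISH")
        rec = classify_cell(self.dapi, [self._flaps(1.0, 5.0)], fish_objs=[fish])
        assert rec.phenotype == "flaps_fish_cell"

    def test_best_overlapping_object_governs_the_call(self):
        # big overlap with low SBR beats small overlap with high SBR
        rec = classify_cell(
            self.dapi, [self._flaps(0.8, 0.5), self._flaps(0.31, 9.0)], th=Thresholds()
        )
        assert rec.phenotype == "unstained_cell"
        assert rec.flaps_overlap == pytest.approx(0.8)


class TestRejectBackground:
    def test_flaps_without_dapi_is_background(self):
        dapi = obj_from_mask(_block(0, 5, 0, 5), role="DAPI")
        lone = obj_from_mask(_block(30, 35, 30, 35), role="FLAPS")
        assert reject_background([lone], [dapi]) == [lone]

    def test_flaps_overlapping_dapi_is_kept(self):
        dapi = obj_from_mask(_block(0, 10, 0, 10), role="DAPI")
        on_cell = obj_from_mask(_block(0, 10, 0, 5), role="FLAPS")
        assert reject_background([on_cell], [dapi]) == []

    def test_no_flaps_objects(self):
        dapi = obj_from_mask(_block(0, 5, 0, 5), role="DAPI")
        assert reject_background([], [dapi]) == []


def _record(phenotype, fov_id="fov_0", probe=None):
    return CellRecord(
        cell_id="c",
        sample_id="s",
        fov_id=fov_id,
        phenotype=phenotype,
        flaps_overlap=1.0 if phenotype.startswith(("flaps", "cyano")) else 0.0,
        flaps_sbr=5.0,
        fish_overlap=1.0 if phenotype == "flaps_fish_cell" else 0.0,
        auto_positive=phenotype == "cyanobacterium",
        probe=probe,
    )


class TestQuantifySample:
    def test_cells_per_litre_arithmetic(self, meta_small):
        # 100 cells in one FOV, filter:FOV ratio 1e4, volume 0.01 L -> 1e8 / L
        meta = AcquisitionMeta(
            pixel_size_um=0.1,
            fov_area_um2=40.96,
            filter_area_um2=40.96e4,
            volume_filtered_L=0.01,
            sample_id="s",
        )
        records = [_record("unstained_cell") for _ in range(100)]
        quant = quantify_sample(records, meta, n_fov=1)
        assert quant.cells_per_L == pytest.approx(1e8)

    def test_fraction_excludes_cyanobacteria(self, meta_small):
        records = (
            [_record("flaps_cell") for _ in range(16)]
            + [_record("unstained_cell") for _ in range(80)]
            + [_record("cyanobacterium") for _ in range(4)]
        )
        quant = quantify_sample(records, meta_small, n_fov=1)
        assert quant.total_cells == 100
        assert quant.frac_flaps_pos == pytest.approx(16 / 96)
        assert quant.n_cyanobacteria == 4

    def test_partition_identity(self, meta_small):
        records = (
            [_record("flaps_cell")] * 7
            + [_record("flaps_fish_cell", probe="CF319a")] * 3
            + [_record("cyanobacterium")] * 2
            + [_record("unstained_cell")] * 8
        )
        quant = quantify_sample(records, meta_small, n_fov=2)
        unstained = quant.total_cells - quant.n_flaps_pos - quant.n_cyanobacteria
        assert quant.n_flaps_pos + quant.n_cyanobacteria + unstained == quant.total_cells
        assert quant.n_fish_flaps_pos == {"CF319a": 3}
        assert quant.n_fish_flaps_pos["CF319a"] <= quant.n_flaps_pos

    def test_zero_cells_flagged_missing(self, meta_small):
        quant = quantify_sample([], meta_small, n_fov=1)
        assert quant.total_cells == 0
        assert np.isnan(quant.frac_flaps_pos)

    def test_wilson_interval_brackets_fraction(self, meta_small):
        records = [_record("flaps_cell")] * 16 + [_record("unstained_cell")] * 84
        quant = quantify_sample(records, meta_small, n_fov=1)
        lo, hi = quant.ci95_frac
        assert lo < quant.frac_flaps_pos < hi


def _quant(timepoint_h, frac, cells):
    from flaps_phenotyper.phenotype import SampleQuant

    return SampleQuant(
        sample_id="s",
        timepoint_h=timepoint_h,
        n_fov=45,
        total_cells=1000,
        cells_per_L=cells,
        n_flaps_pos=int(frac * 1000),
        frac_flaps_pos=frac,
        n_fish_flaps_pos={},
        n_cyanobacteria=0,
        n_background_particles=0,
        ci95_frac=(frac - 0.02, frac + 0.02),
    )


class TestTimecourse:
    def test_dilution_flag_on_drop_with_growth(self):
        quants = [_quant(0, 0.2, 1e9), _quant(24, 0.1, 2e9)]
        _, flags = timecourse_summary(quants)
        assert flags.tolist() == [True]

    def test_constant_series_unflagged(self):
        quants = [_quant(t, 0.2, 1e9) for t in (0, 24, 48)]
        _, flags = timecourse_summary(quants)
        assert not flags.any()

    def test_rising_fraction_never_flagged(self):
        quants = [_quant(0, 0.1, 1e9), _quant(24, 0.3, 3e9)]
        _, flags = timecourse_summary(quants)
        assert not flags.any()

    def test_unordered_timepoints_rejected(self):
        with pytest.raises(InputError):
            timecourse_summary([_quant(24, 0.2, 1e9), _quant(0, 0.1, 1e9)])


class TestMonotonicity:
    def test_raising_thresholds_never_increases_positives(self):
        fov, _ = simulate_field(
            SimFieldConfig(seed=31, shape=(192, 192), n_cells=30, noise_sd=8.0)
        )
        det = detect_field(fov, SegmentationParams())

        def n_pos(th):
            recs, _ = classify_field(det, th)
            return sum(r.phenotype in ("flaps_cell", "flaps_fish_cell") for r in recs)

        counts_ov = [n_pos(Thresholds(min_overlap=v)) for v in np.linspace(0.05, 0.95, 5)]
        assert counts_ov == sorted(counts_ov, reverse=True)
        counts_sbr = [n_pos(Thresholds(min_sbr=v)) for v in (0.5, 2, 5, 10, 20)]
        assert counts_sbr == sorted(counts_sbr, reverse=True)


class TestFieldEquivalence:
    def test_classify_field_matches_per_cell_classification(self):
        """Fast label-raster path equals object-by-object classify_cell."""
        fov, _ = simulate_field(
            SimFieldConfig(seed=33, shape=(192, 192), n_cells=20, noise_sd=8.0)
        )
        det = detect_field(fov, SegmentationParams())
        recs, _ = classify_field(det)
        for rec in recs:
            slow = classify_cell(
                rec.dapi_object,
                det["FLAPS"],
                det.get("FISH", []),
                det.get("AUTO", []),
            )
            assert slow.phenotype == rec.phenotype
            assert slow.flaps_overlap == pytest.approx(rec.flaps_overlap)
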