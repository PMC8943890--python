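import math

import numpy as np
import pytest
from scipy import stats

from srsphasor import (
    Image2D,
    PhasorROI,
    QuantRecord,
    TestResult,
    WavenumberAxis,
    dose_response_table,
    peak_ratio,
    per_cell_mean_intensity,
    percent_area,
    percent_cells_with_droplets,
    students_t_test,
)
from srsphasor.phasor import SegmentationMap, SpectrumProfile
from srsphasor.quant import cell_instances_from_mask


def seg_from_labels(label_array, roi_names):
    rois = [PhasorROI(name, rect=(0, 1, 0, 1)) for name in roi_names]
    return SegmentationMap(labels=Image2D(np.asarray(label_array, np.int32),
                                          meaning="label"),
                           roi_list=rois)


def profile_from(wavenumbers, intensities, normalized=False):
    return SpectrumProfile(
        wavenumbers=WavenumberAxis(np.asarray(wavenumbers, float)),
        mean_intensity=np.asarray(intensities, float),
        n_pixels=1, normalized=normalized)


class TestPercentArea:
    def test_quarter_coverage(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[:5, :5] = 1
        seg = seg_from_labels(labels, ["droplet"])
        mask = Image2D(np.ones((10, 10), np.uint8), meaning="mask")
        assert percent_area(seg, "droplet", mask) == pytest.approx(25.0)

    def test_no_droplets_is_zero(self):
        seg = seg_from_labels(np.zeros((5, 5), np.int32), ["droplet"])
        mask = Image2D(np.ones((5, 5), np.uint8), meaning="mask")
        assert percent_area(seg, "droplet", mask) == 0.0

    def test_droplets_outside_mask_not_counted(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, :] = 1
        mask = np.zeros((4, 4), np.uint8)
        mask[1:, :] = 1
        seg = seg_from_labels(labels, ["droplet"])
        assert percent_area(seg, "droplet",
                            Image2D(mask, meaning="mask")) == 0.0

    def test_empty_mask_rejected(self):
        seg = seg_from_labels(np.zeros((5, 5), np.int32), ["droplet"])
        mask = Image2D(np.zeros((5, 5), np.uint8), meaning="mask")
        with pytest.raises(ValueError, match="empty"):
            percent_area(seg, "droplet", mask)

    def test_invariant_to_other_class_relabelling(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[:2, :2] = 1   # droplet
        labels[3:, 3:] = 2   # other
        seg_a = seg_from_labels(labels, ["droplet", "cytoplasm"])
        relabeled = labels.copy()
        relabeled[relabeled == 2] = 0
        seg_b = seg_from_labels(relabeled, ["droplet", "cytoplasm"])
        mask = Image2D(np.ones((6, 6), np.uint8), meaning="mask")
        assert (percent_area(seg_a, "droplet", mask)
                == percent_area(seg_b, "droplet", mask))


class TestPeakRatio:
    def test_equal_heights_give_unity(self):
        wn = np.linspace(2960, 3020, 7)
        profile = profile_from(wn, np.full(7, 2.0))
        assert peak_ratio(profile) == pytest.approx(1.0)

    def test_linear_interpolation_midpoint(self):
        profile = profile_from([2960, 2970], [1.0, 3.0])
        # interpolated height at 2965 is 2.0
        assert peak_ratio(profile, num_wavenumber=2970,
                          den_wavenumber=2965) == pytest.approx(3.0 / 2.0)

    def test_scale_invariance(self):
        wn = np.linspace(2900, 3050, 26)
        spectrum = 1.0 + np.sin(wn / 40.0) ** 2
        a = peak_ratio(profile_from(wn, spectrum))
        b = peak_ratio(profile_from(wn, 7.3 * spectrum))
        assert a == pytest.approx(b, rel=1e-12)

    def test_out_of_range_wavenumber_rejected(self):
        profile = profile_from([2960, 2970], [1.0, 2.0])
        with pytest.raises(ValueError, match="outside"):
            peak_ratio(profile)  # 3015 not on this axis

    def test_nonpositive_denominator_rejected(self):
        wn = np.linspace(2960, 3020, 7)
        values = np.where(wn < 3000, 0.0, 1.0)
        profile = profile_from(wn, values)
        with pytest.raises(ValueError, match="non-positive"):
            peak_ratio(profile)

    def test_normalized_profile_rejected(self):
        wn = np.linspace(2960, 3020, 7)
        profile = profile_from(wn, np.linspace(0, 1, 7), normalized=True)
        with pytest.raises(ValueError, match="un-normalised"):
            peak_ratio(profile)


class TestPercentCellsWithDroplets:
    def _instances(self):
        cells = np.zeros((9, 9), dtype=np.int32)
        cells[0:3, :] = 1
        cells[3:6, :] = 2
        cells[6:9, :] = 3
        return Image2D(cells, meaning="label")

    def test_one_of_three(self):
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[0, 0:4] = 1  # 4 droplet px in cell 1 only
        seg = seg_from_labels(labels, ["droplet"])
        assert percent_cells_with_droplets(
            self._instances(), seg, "droplet") == pytest.approx(100 / 3)

    def test_all_cells(self):
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[0, :4] = labels[3, :4] = labels[6, :4] = 1
        seg = seg_from_labels(labels, ["droplet"])
        assert percent_cells_with_droplets(
            self._instances(), seg, "droplet") == 100.0

    def test_minimum_pixel_gate(self):
        labels = np.zeros((9, 9), dtype=np.int32)
        labels[0, 0:3] = 1  # only 3 px: below the default gate of 4
        seg = seg_from_labels(labels, ["droplet"])
        assert percent_cells_with_droplets(
            self._instances(), seg, "droplet") == 0.0
        assert percent_cells_with_droplets(
            self._instances(), seg, "droplet", min_droplet_px=3) > 0.0

    def test_no_cells_rejected(self):
        seg = seg_from_labels(np.zeros((4, 4), np.int32), ["droplet"])
        empty = Image2D(np.zeros((4, 4), np.int32), meaning="label")
        with pytest.raises(ValueError, match="no cells"):
            percent_cells_with_droplets(empty, seg, "droplet")

    def test_connected_components_fallback(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[0:3, 0:3] = 1
        mask[5:8, 5:8] = 1
        instances = cell_instances_from_mask(Image2D(mask, meaning="mask"))
        assert instances.values.max() == 2


class TestPerCellMeanIntensity:
    def test_hand_example(self):
        projection = Image2D(np.array([[2.0, 4.0], [0.0, 0.0]]))
        cells = Image2D(np.array([[1, 1], [0, 0]], np.int32), meaning="label")
        assert per_cell_mean_intensity(projection, cells) == [(1, 3.0)]

    def test_constant_image(self):
        projection = Image2D(np.full((6, 6), 7.0))
        cells = np.zeros((6, 6), np.int32)
        cells[:3] = 1
        cells[3:] = 2
        result = per_cell_mean_intensity(projection,
                                         Image2D(cells, meaning="label"))
        assert result == [(1, 7.0), (2, 7.0)]

    def test_matches_naive_loop(self, rng):
        projection = Image2D(rng.random((20, 20)))
        cells = rng.integers(0, 5, size=(20, 20)).astype(np.int32)
        instances = Image2D(cells, meaning="label")
        result = dict(per_cell_mean_intensity(projection, instances))
        for cell_id in range(1, 5):
            member = cells == cell_id
            if member.any():
                expected = projection.values[member].mean()
                assert result[cell_id] == pytest.approx(expected, rel=1e-12)

    def test_empty_cell_skipped_with_warning(self):
        projection = Image2D(np.ones((4, 4)))
        cells = np.zeros((4, 4), np.int32)
        cells[0, 0] = 2  # id 1 has no pixels
        with pytest.warns(UserWarning, match="cell 1"):
            result = per_cell_mean_intensity(projection,
                                             Image2D(cells, meaning="label"))
        assert result == [(2, 1.0)]


class TestStudentsTTest:
    def test_identical_groups(self):
        result = students_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.statistic == 0.0
        assert result.p_value == 1.0
        assert result.stars == "ns"

    def test_textbook_example(self):
        result = students_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert result.statistic == pytest.approx(-1.224745, abs=1e-6)
        assert result.df == 4
        assert result.p_value == pytest.approx(0.287904, abs=1e-4)
        assert result.stars == "ns"

    def test_clear_separation_is_highly_significant(self):
        result = students_t_test([0.0, 0.0, 0.0], [10.0, 10.0, 10.0001])
        assert result.p_value < 0.01
        assert result.stars == "**"

    def test_antisymmetric_in_group_order(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(loc=0.5, size=4)
        fwd = students_t_test(a, b)
        rev = students_t_test(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic, rel=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(2, 9)))
            b = rng.normal(loc=rng.normal(), size=int(rng.integers(2, 9)))
            ours = students_t_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            students_t_test([1.0], [1.0, 2.0])

    def test_zero_variance_equal_means(self):
        result = students_t_test([5.0, 5.0], [5.0, 5.0])
        assert result.statistic == 0.0 and result.p_value == 1.0

    @pytest.mark.parametrize("p,stars", [
        (0.049, "*"), (0.05, "*"), (0.051, "ns"),
        (0.01, "**"), (0.009, "**"), (0.2, "ns"),
    ])
    def test_star_thresholds(self, p, stars):
        assert TestResult(statistic=1.0, df=4, p_value=p).stars == stars


class TestDoseResponseTable:
    @staticmethod
    def record(condition, replicate, pa, ratio=0.75):
        return QuantRecord(condition=condition, replicate=replicate,
                           percent_area=pa, peak_ratio=ratio, n_cells=8,
                           percent_cells_with_droplets=50.0,
                           mean_cell_intensity=1.0)

    def test_mean_and_sd(self):
        records = [self.record("control", i, 10.0) for i in range(3)]
        records += [self.record("high", i, 12.0 + i) for i in range(3)]
        summary, tests = dose_response_table(records, "control")
        control = summary[summary.condition == "control"].iloc[0]
        assert control.percent_area_mean == 10.0
        assert control.percent_area_sd == 0.0
        assert "high" in tests

    def test_dose_identical_to_control_not_significant(self):
        records = [self.record("control", i, v)
                   for i, v in enumerate([9.0, 10.0, 11.0])]
        records += [self.record("dose", i, v)
                    for i, v in enumerate([9.0, 10.0, 11.0])]
        _, tests = dose_response_table(records, "control")
        assert tests["dose"].stars == "ns"

    def test_missing_control_rejected(self):
        records = [self.record("dose", i, 5.0) for i in range(3)]
        with pytest.raises(ValueError, match="control"):
            dose_response_table(records, "control")

    def test_single_replicate_rejected(self):
        records = [self.record("control", 0, 5.0),
                   self.record("control", 1, 5.0),
                   self.record("dose", 0, 6.0)]
        with pytest.raises(ValueError, match="replicates"):
            dose_response_table(records, "control")


class TestQuantRecordValidation:
    def test_percent_bounds_enforced(self):
        with pytest.raises(ValueError):
            TestDoseResponseTable.record("c", 0, 120.0)

    def test_nan_peak_ratio_allowed(self):
        record = TestDoseResponseTable.record("c", 0, 1.0, ratio=math.nan)
        assert math.isnan(record.peak_ratio)
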