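"""Dilation, per-cell classification and image-level overlap summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from myoslice.classify import (
    CellRecord,
    assign_class,
    classify_cells,
    dilate_mask,
    summarize_image,
)
from myoslice.segmentation import CellLabelMap


class TestDilateMask:
    def test_radius_zero_is_identity(self, rng):
        mask = rng.random((20, 20)) < 0.3
        np.testing.assert_array_equal(dilate_mask(mask, 0), mask)

    def test_single_pixel_becomes_euclidean_disk(self):
        mask = np.zeros((21, 21), bool)
        mask[10, 10] = True
        out = dilate_mask(mask, 4)
        yy, xx = np.mgrid[0:21, 0:21]
        expected = (yy - 10) ** 2 + (xx - 10) ** 2 <= 16
        np.testing.assert_array_equal(out, expected)

    def test_matches_structuring_element_dilation_on_large_grids(self, rng):
        # the EDT shortcut used above 64k pixels must equal the
        # structuring-element definition
        mask = rng.random((300, 300)) < 0.01
        np.testing.assert_array_equal(
            dilate_mask(mask, 3), binary_dilation(mask, structure=disk(3))
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(mask=hnp.arrays(np.bool_, (15, 15)), radius=st.integers(0, 5))
    def test_dilation_is_extensive(self, mask, radius):
        out = dilate_mask(mask, radius)
        assert (out | mask == out).all()


class TestAssignClass:
    @pytest.mark.parametrize(
        "f_ryr,f_dx,expected",
        [
            (0.16, 0.0, "live"),          # just over the RyR threshold
            (0.15, 0.0, "live"),          # >= is inclusive
            (0.1499, 0.25, "dead"),
            (0.5, 0.5, "double_positive"),
            (0.0, 0.0, "double_negative"),
            (0.149, 0.199, "double_negative"),
            (0.15, 0.2, "double_positive"),
        ],
    )
    def test_threshold_rules(self, f_ryr, f_dx, expected):
        assert assign_class(f_ryr, f_dx) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(f_ryr=st.floats(0, 1), f_dx=st.floats(0, 1))
    def test_classes_partition_the_fraction_space(self, f_ryr, f_dx):
        cls = assign_class(f_ryr, f_dx)
        assert cls in ("live", "dead", "double_positive", "double_negative")
        # raising the RyR threshold can only shrink the RyR-positive set
        stricter = assign_class(f_ryr, f_dx, theta_ryr=0.5)
        if stricter in ("live", "double_positive"):
            assert cls in ("live", "double_positive")


def _toy_scene():
    """Two 10x10 segments: one mostly RyR, one mostly dextran."""
    labels = np.zeros((10, 22), np.int32)
    labels[:, :10] = 1
    labels[:, 12:] = 2
    ryr = np.zeros((10, 22), bool)
    ryr[:, :4] = True  # 40 of 100 px of cell 1
    dex = np.zeros((10, 22), bool)
    dex[:, 12:17] = True  # 50 of 100 px of cell 2
    return CellLabelMap(labels, 0.1), ryr, dex


class TestClassifyCells:
    def test_fractions_and_classes_on_constructed_segments(self):
        labels, ryr, dex = _toy_scene()
        records = classify_cells(labels, ryr, dex, r_ryr_px=0, r_dx_px=0)
        rec1, rec2 = records
        assert rec1.f_ryr == pytest.approx(0.4)
        assert rec1.f_dextran == 0.0
        assert rec1.cell_class == "live"
        assert rec2.f_dextran == pytest.approx(0.5)
        assert rec2.cell_class == "dead"
        assert rec1.raw_ryr_density_pct == pytest.approx(40.0)
        assert rec1.area_um2 == pytest.approx(1.0)

    def test_empty_masks_yield_double_negative_everywhere(self):
        labels, _, _ = _toy_scene()
        empty = np.zeros(labels.labels.shape, bool)
        records = classify_cells(labels, empty, empty)
        assert all(r.cell_class == "double_negative" for r in records)

    def test_empty_label_map_yields_no_records(self):
        labels = CellLabelMap(np.zeros((5, 5), np.int32), 0.1)
        assert classify_cells(labels, np.zeros((5, 5), bool), None) == []

    def test_dilation_radii_affect_the_fractions(self):
        labels, ryr, dex = _toy_scene()
        raw = classify_cells(labels, ryr, dex, r_ryr_px=0, r_dx_px=0)
        dil = classify_cells(labels, ryr, dex, r_ryr_px=4, r_dx_px=3)
        assert dil[0].f_ryr > raw[0].f_ryr
        assert dil[1].f_dextran > raw[1].f_dextran

    def test_ground_truth_classes_are_recovered(self, result200):
        assert result200.truth_accuracy >= 0.9

    def test_raising_theta_never_increases_ryr_positive_count(self, result200):
        base = sum(r.ryr_positive for r in result200.records)
        f = np.array([r.f_ryr for r in result200.records])
        for theta in (0.2, 0.4, 0.8):
            assert (f >= theta).sum() <= base


class TestSummarizeImage:
    def _records(self, spec):
        out = []
        for i, cls in enumerate(spec, start=1):
            f_ryr = 0.5 if cls in ("live", "double_positive") else 0.0
            f_dx = 0.5 if cls in ("dead", "double_positive") else 0.0
            out.append(
                CellRecord(cell_id=i, area_px=100, area_um2=1.0, f_ryr=f_ryr,
                           f_dextran=f_dx, cell_class=cls,
                           raw_ryr_density_pct=0.0)
            )
        return out

    def test_union_referenced_cell_fraction(self):
        # RyR+ = {A, B, C}, Dx+ = {C, D}: overlap C over union {A,B,C,D}
        records = self._records(["live", "live", "double_positive", "dead"])
        labels = CellLabelMap(np.zeros((4, 4), np.int32), 0.1)
        s = summarize_image(records, np.zeros((4, 4), bool),
                            np.zeros((4, 4), bool), labels)
        assert s.double_positive_cell_fraction == pytest.approx(0.25)

    def test_no_double_positives_gives_zero_fraction(self):
        records = self._records(["live", "dead"])
        labels = CellLabelMap(np.zeros((2, 2), np.int32), 0.1)
        s = summarize_image(records, np.zeros((2, 2), bool),
                            np.zeros((2, 2), bool), labels)
        assert s.double_positive_cell_fraction == 0.0

    def test_empty_union_is_flagged_undefined(self):
        records = self._records(["double_negative"])
        labels = CellLabelMap(np.zeros((2, 2), np.int32), 0.1)
        s = summarize_image(records, np.zeros((2, 2), bool),
                            np.zeros((2, 2), bool), labels)
        assert s.double_positive_cell_fraction is None
        assert s.double_positive_pixel_fraction is None

    def test_pixel_fraction_on_dilated_masks_within_cells(self):
        labels, ryr, dex = _toy_scene()
        records = classify_cells(labels, ryr, dex, r_ryr_px=0, r_dx_px=0)
        dex2 = dex.copy()
        dex2[:, :2] = True  # overlap 20 px with the 40 RyR px in cell 1
        s = summarize_image(records, ryr, dex2, labels)
        # union inside labels: 40 + 50 + 20 - 20 ... ryr 40, dex-in-labels 70
        assert s.double_positive_pixel_fraction == pytest.approx(20 / 90)

    def test_pearson_correlation_bounds(self):
        labels, _, _ = _toy_scene()
        chan = np.random.default_rng(0).normal(100, 20, labels.labels.shape)
        records = self._records(["live"])
        s_pos = summarize_image(records, np.zeros_like(chan, bool),
                                np.zeros_like(chan, bool), labels,
                                ryr_channel=chan, dextran_channel=chan)
        s_neg = summarize_image(records, np.zeros_like(chan, bool),
                                np.zeros_like(chan, bool), labels,
                                ryr_channel=chan, dextran_channel=-chan)
        assert s_pos.pearson_r == pytest.approx(1.0)
        assert s_neg.pearson_r == pytest.approx(-1.0)

    def test_mutually_exclusive_states_have_little_pixel_overlap(
        self, result_exclusive
    ):
        s = result_exclusive.summary
        assert s.double_positive_pixel_fraction is not None
        assert s.double_positive_pixel_fraction < 0.05
        assert s.pearson_r < 0  # complementary stains anti-correlate
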