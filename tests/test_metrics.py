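"""t-system extraction and morphometry, nucleus shape, RyR pattern."""

import math

import numpy as np
import pytest
from scipy.ndimage import binary_closing
from skimage.morphology import disk

from myoslice.metrics import (
    extract_t_system,
    nucleus_metrics,
    ryr_pattern_metrics,
    t_system_metrics,
)
from myoslice.segmentation import CellLabelMap


def _rect_cell_with_lines(n_lines=3, line_width=2, shape=(60, 120)):
    """Rectangular cell crossed by thin vertical WGA lines."""
    labels = np.zeros(shape, np.int32)
    labels[5:-5, 5:-5] = 1
    wga = np.zeros(shape, bool)
    wga[:5, :] = wga[-5:, :] = True
    wga[:, :5] = wga[:, -5:] = True
    cols = np.linspace(25, shape[1] - 25, n_lines).astype(int)
    for c in cols:
        wga[5:-5, c:c + line_width] = True
        labels[5:-5, c:c + line_width] = 0  # lines are WGA, not interior
    return CellLabelMap(labels, 0.1), wga, cols


class TestExtractTSystem:
    def test_no_intracellular_wga_gives_empty_t_system(self):
        labels = CellLabelMap(np.zeros((40, 40), np.int32), 0.1)
        labels.labels[5:35, 5:35] = 1
        wga = np.zeros((40, 40), bool)
        wga[:5, :] = True
        t = extract_t_system(labels, wga, closing_radius_px=5)
        assert not t.any()

    def test_thin_lines_inside_the_cell_are_recovered(self):
        labels, wga, cols = _rect_cell_with_lines()
        t = extract_t_system(labels, wga, closing_radius_px=5)
        # the closing disk cannot reach the single end row at each slit
        # mouth, so compare away from the mouths
        expected = np.zeros_like(wga)
        for c in cols:
            expected[6:-6, c:c + 2] = True
        np.testing.assert_array_equal((t > 0)[6:-6], expected[6:-6])
        assert not ((t > 0) & ~wga).any()

    def test_matches_brute_force_closing_difference(self):
        labels, wga, _ = _rect_cell_with_lines(n_lines=2)
        t = extract_t_system(labels, wga, closing_radius_px=5)
        interior = labels.labels == 1
        # closing on an unbounded (background-padded) domain
        closed = binary_closing(np.pad(interior, 8), structure=disk(5))[8:-8, 8:-8]
        expected = closed & ~interior & wga
        np.testing.assert_array_equal(t > 0, expected)

    def test_inclusion_wider_than_twice_the_radius_is_not_recovered(self):
        labels, wga, _ = _rect_cell_with_lines(n_lines=0)
        wga[5:-5, 50:64] = True  # 1.4 µm wide inclusion, radius 0.5 µm
        labels.labels[5:-5, 50:64] = 0
        t = extract_t_system(labels, wga, closing_radius_px=5)
        assert not t[:, 52:62].any()

    def test_zero_radius_warns_and_returns_empty(self):
        labels, wga, _ = _rect_cell_with_lines()
        with pytest.warns(RuntimeWarning, match="radius 0"):
            t = extract_t_system(labels, wga, closing_radius_px=0)
        assert not t.any()


class TestTSystemMetrics:
    def test_full_coverage_gives_zero_distance(self):
        interior = np.ones((20, 20), bool)
        m = t_system_metrics(interior, interior.copy(), 0.1)
        assert m.delta_tt_um == 0.0

    def test_parallel_lines_spaced_2um_give_quarter_spacing(self):
        # lines every 2 µm across a long cell; continuum mean distance is
        # spacing / 4 = 0.5 µm
        interior = np.ones((200, 1001), bool)
        t_mask = np.zeros((200, 1001), bool)
        t_mask[:, ::20] = True
        m = t_system_metrics(interior, t_mask, 0.1)
        assert m.delta_tt_um == pytest.approx(0.5, abs=0.05)

    def test_doubling_line_density_halves_the_distance(self):
        interior = np.ones((200, 1001), bool)
        sparse = np.zeros_like(interior)
        sparse[:, ::40] = True
        dense = np.zeros_like(interior)
        dense[:, ::20] = True
        m_sparse = t_system_metrics(interior, sparse, 0.1)
        m_dense = t_system_metrics(interior, dense, 0.1)
        assert m_dense.delta_tt_um < m_sparse.delta_tt_um
        assert m_dense.delta_tt_um == pytest.approx(
            m_sparse.delta_tt_um / 2, rel=0.1
        )

    def test_empty_t_system_is_flagged_undefined(self):
        interior = np.ones((10, 10), bool)
        m = t_system_metrics(interior, np.zeros_like(interior), 0.1)
        assert m.delta_tt_um is None
        assert m.skeleton_density == 0.0

    def test_single_line_skeleton_length(self):
        interior = np.zeros((30, 120), bool)
        interior[5:25, 5:115] = True
        t_mask = np.zeros_like(interior)
        t_mask[5:25, 60:63] = True  # 3 px wide, 20 px long line
        m = t_system_metrics(interior & ~t_mask, t_mask, 0.1)
        skel_px = m.skeleton_density * (interior | t_mask).sum()
        assert abs(skel_px - 20) <= 3  # 1-px centerline, end effects allowed

    def test_skeleton_density_is_invariant_to_moderate_line_thickening(self):
        interior = np.zeros((40, 200), bool)
        interior[5:35, 5:195] = True
        thin = np.zeros_like(interior)
        thin[5:35, 100] = True
        thick = np.zeros_like(interior)
        thick[5:35, 99:102] = True
        m_thin = t_system_metrics(interior, thin, 0.1)
        m_thick = t_system_metrics(interior, thick, 0.1)
        n_thin = m_thin.skeleton_density * (interior | thin).sum()
        n_thick = m_thick.skeleton_density * (interior | thick).sum()
        assert abs(n_thin - n_thick) <= 2


def _ellipse_mask(shape, center, a_px, b_px, angle_deg):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    th = math.radians(angle_deg)
    u = (xx - center[1]) * math.cos(th) + (yy - center[0]) * math.sin(th)
    v = (yy - center[0]) * math.cos(th) - (xx - center[1]) * math.sin(th)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


class TestNucleusMetrics:
    def _whole_image_cell(self, shape):
        return CellLabelMap(np.ones(shape, np.int32), 0.1)

    def test_disk_area_and_circularity(self):
        mask = _ellipse_mask((100, 100), (50, 50), 20, 20, 0)
        nuc = nucleus_metrics(mask, self._whole_image_cell((100, 100)), 0.1)[0]
        assert nuc.area_um2 == pytest.approx(4 * math.pi, rel=0.03)
        assert nuc.circularity >= 0.97

    def test_two_to_one_ellipse_circularity(self):
        mask = _ellipse_mask((100, 120), (50, 60), 40, 20, 0)
        nuc = nucleus_metrics(mask, self._whole_image_cell((100, 120)), 0.1)[0]
        assert nuc.circularity == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("angle", [0, 17, 45, 60, 123])
    def test_circularity_is_rotation_invariant(self, angle):
        mask = _ellipse_mask((120, 120), (60, 60), 40, 20, angle)
        nuc = nucleus_metrics(mask, self._whole_image_cell((120, 120)), 0.1)[0]
        assert nuc.circularity == pytest.approx(0.5, rel=0.02)

    def test_two_nuclei_share_one_parent_cell(self):
        labels = CellLabelMap(np.zeros((80, 200), np.int32), 0.1)
        labels.labels[5:75, 5:195] = 1
        mask = _ellipse_mask((80, 200), (40, 55), 25, 15, 0)
        mask |= _ellipse_mask((80, 200), (40, 140), 25, 15, 0)
        nuclei = nucleus_metrics(mask, labels, 0.1)
        assert len(nuclei) == 2
        assert all(n.parent_cell_id == 1 for n in nuclei)

    def test_orphan_nucleus_keeps_background_parent(self):
        labels = CellLabelMap(np.zeros((80, 80), np.int32), 0.1)
        mask = _ellipse_mask((80, 80), (40, 40), 25, 18, 0)
        nuclei = nucleus_metrics(mask, labels, 0.1)
        assert nuclei[0].parent_cell_id == 0

    def test_speckle_below_the_area_floor_is_ignored(self):
        labels = self._whole_image_cell((50, 50))
        mask = np.zeros((50, 50), bool)
        mask[10:12, 10:12] = True  # 0.04 µm²
        assert nucleus_metrics(mask, labels, 0.1) == []


class TestRyRPatternMetrics:
    def _grating_cell(self, period_um=2.0, shape=(200, 500), jitter_sd_um=0.0,
                      seed=0):
        """Rows of RyR-like clusters with optional positional scrambling."""
        rng = np.random.default_rng(seed)
        img = np.zeros(shape, np.float32)
        us = np.arange(5, shape[1] * 0.1 - 1, period_um)
        vs = np.arange(1.0, shape[0] * 0.1 - 0.5, 0.8)
        uu = np.repeat(us, vs.size) + rng.normal(0, jitter_sd_um, us.size * vs.size)
        vv = np.tile(vs, us.size) + rng.normal(0, jitter_sd_um, us.size * vs.size)
        ci = np.clip(np.rint(uu / 0.1).astype(int), 0, shape[1] - 1)
        ri = np.clip(np.rint(vv / 0.1).astype(int), 0, shape[0] - 1)
        np.add.at(img, (ri, ci), 1000.0)
        from scipy.ndimage import gaussian_filter

        return gaussian_filter(img, 1.5)

    def test_cosine_grating_concentrates_energy_in_the_band(self):
        shape = (200, 500)  # 20 x 50 µm cell
        x_um = np.arange(shape[1]) * 0.1
        img = np.tile(100 + 50 * np.cos(2 * np.pi * x_um / 2.0), (shape[0], 1))
        m = ryr_pattern_metrics(img, img > 100, np.ones(shape, bool), 0.1)
        assert m.regularity >= 0.9

    def test_constant_intensity_has_zero_regularity(self):
        shape = (120, 300)
        m = ryr_pattern_metrics(np.full(shape, 55.0), np.zeros(shape, bool),
                                np.ones(shape, bool), 0.1)
        assert m.regularity == 0.0
        assert m.density_pct == 0.0

    def test_jittered_clusters_score_below_matched_regular_cells(self):
        losses = 0
        for seed in range(10):
            regular = self._grating_cell(seed=seed)
            jittered = self._grating_cell(jitter_sd_um=1.0, seed=seed)
            shape = regular.shape
            interior = np.ones(shape, bool)
            r_reg = ryr_pattern_metrics(regular, regular > 50, interior, 0.1)
            r_jit = ryr_pattern_metrics(jittered, jittered > 50, interior, 0.1)
            losses += r_jit.regularity < r_reg.regularity
        assert losses == 10

    def test_regularity_is_invariant_to_affine_intensity_rescaling(self):
        img = self._grating_cell(seed=4)
        interior = np.ones(img.shape, bool)
        a = ryr_pattern_metrics(img, img > 50, interior, 0.1)
        b = ryr_pattern_metrics(7.0 * img + 300.0, img > 50, interior, 0.1)
        assert a.regularity == pytest.approx(b.regularity, rel=1e-6)

    def test_small_cells_are_flagged_not_evaluable(self):
        shape = (30, 40)  # 3 x 4 µm: cannot resolve two 2.5 µm periods
        interior = np.zeros(shape, bool)
        interior[5:25, 5:35] = True
        m = ryr_pattern_metrics(np.ones(shape), np.zeros(shape, bool),
                                interior, 0.1)
        assert not m.evaluable
        assert m.regularity is None

    def test_density_counts_non_dilated_positive_pixels(self):
        shape = (40, 100)
        interior = np.ones(shape, bool)
        mask = np.zeros(shape, bool)
        mask[:, :25] = True
        m = ryr_pattern_metrics(np.ones(shape), mask, interior, 0.1)
        assert m.density_pct == pytest.approx(25.0)

    def test_class_orderings_on_synthetic_tissue(self, result200):
        """Live cells show regular striations; dying (double-positive)
        cells lose regularity but keep density above dead cells."""
        by_class = {}
        for r in result200.records:
            by_class.setdefault(r.cell_class, []).append(r)
        reg = {c: np.mean([r.ryr_regularity for r in rs
                           if r.ryr_regularity is not None])
               for c, rs in by_class.items()}
        dens = {c: np.mean([r.raw_ryr_density_pct for r in rs])
                for c, rs in by_class.items()}
        assert reg["live"] > reg["double_positive"]
        assert dens["double_positive"] > dens["dead"]

    def test_delta_tt_reflects_tubule_density(self, result200):
        by_class = {}
        for r in result200.records:
            if r.delta_tt_um is not None:
                by_class.setdefault(r.cell_class, []).append(r.delta_tt_um)
        assert np.mean(by_class["live"]) < np.mean(by_class["dead"])
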