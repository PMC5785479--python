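"""Tumor-area segmentation, polygon measurement and metastasis scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skimage.draw import disk as draw_disk

from xenoquant import (
    NO_CELLS, LOCALIZED, INVADED, YolkRoi, MetastasisConfig, EmbryoPhenotype,
    NoContrastError, segment_tumor_area, polygon_area, combine_area,
    count_dispersed_cells, classify_embryo, cohort_table,
)


def _disk_image(shape=(200, 200), center=(100, 100), radius=20, value=255.0):
    img = np.zeros(shape)
    rr, cc = draw_disk(center, radius, shape=shape)
    img[rr, cc] = value
    return img


ROI = YolkRoi(center=(100, 100), radii=(60, 60))


class TestSegmentTumorArea:
    def test_blank_image_has_zero_area(self):
        area, mask = segment_tumor_area(np.zeros((50, 50)), YolkRoi((25, 25), (10, 10)))
        assert area == 0 and not mask.any()

    def test_disk_area_matches_analytic_circle(self):
        area, _ = segment_tumor_area(_disk_image(radius=20), ROI)
        assert abs(area - math.pi * 20 ** 2) / (math.pi * 20 ** 2) < 0.05

    def test_component_outside_roi_not_counted(self):
        img = _disk_image(radius=15)
        rr, cc = draw_disk((20, 180), 8, shape=img.shape)
        img[rr, cc] = 255.0
        area_one, _ = segment_tumor_area(_disk_image(radius=15), ROI)
        area_two, _ = segment_tumor_area(img, ROI)
        assert area_two == area_one

    def test_component_spilling_over_roi_counted_in_full(self):
        # disk centered on the ROI boundary still belongs to the tumor
        img = _disk_image(center=(100, 158), radius=10)
        area, _ = segment_tumor_area(img, ROI)
        assert area > 300  # full disk, not just the in-ROI half

    def test_monotone_in_blob_radius(self):
        areas = [segment_tumor_area(_disk_image(radius=r), ROI)[0]
                 for r in (5, 10, 20, 40)]
        assert areas == sorted(areas) and areas[0] > 0

    def test_saturated_uniform_roi_raises_no_contrast(self):
        with pytest.raises(NoContrastError):
            segment_tumor_area(np.full((50, 50), 200.0),
                               YolkRoi((25, 25), (10, 10)))

    def test_low_contrast_noise_scores_empty(self, rng):
        img = np.clip(rng.normal(20, 4, (80, 80)), 0, None)
        area, _ = segment_tumor_area(img, YolkRoi((40, 40), (20, 20)))
        assert area == 0

    def test_fixed_threshold_mode(self):
        img = _disk_image(radius=10, value=120.0)
        cfg = MetastasisConfig(threshold_mode="fixed", threshold_value=100.0)
        area, _ = segment_tumor_area(img, ROI, cfg)
        assert area == pytest.approx(math.pi * 100, rel=0.05)


class TestPolygonArea:
    def test_lattice_polygons_exact(self):
        assert polygon_area([(0, 0), (1, 0), (1, 1), (0, 1)]) == 1.0
        assert polygon_area([(0, 0), (4, 0), (0, 3)]) == 6.0

    def test_orientation_independent(self):
        square = [(0, 0), (2, 0), (2, 2), (0, 2)]
        assert polygon_area(square) == polygon_area(square[::-1]) == 4.0

    def test_too_few_vertices_refused(self):
        with pytest.raises(ValueError):
            polygon_area([(0, 0), (1, 1)])

    def test_random_simple_polygon_matches_monte_carlo(self, rng):
        # star-shaped construction guarantees a simple polygon
        angles = np.sort(rng.uniform(0, 2 * math.pi, 12))
        radii = rng.uniform(1.0, 5.0, 12)
        verts = np.c_[radii * np.cos(angles), radii * np.sin(angles)]
        area = polygon_area(verts)

        from shapely import contains_xy
        from shapely.geometry import Polygon
        poly = Polygon(verts)
        lo, hi = verts.min(axis=0), verts.max(axis=0)
        pts = rng.uniform(lo, hi, size=(200_000, 2))
        box = np.prod(hi - lo)
        mc = box * contains_xy(poly, pts[:, 0], pts[:, 1]).mean()
        assert abs(area - mc) / mc < 0.01

    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
                    min_size=3, max_size=8))
    def test_translation_invariance(self, verts):
        shifted = [(x + 100.0, y - 50.0) for x, y in verts]
        assert polygon_area(verts) == pytest.approx(polygon_area(shifted),
                                                    abs=1e-6)


class TestCombineArea:
    def test_arithmetic_mean(self):
        assert combine_area(100, 120) == 110
        assert combine_area(7.0, 7.0) == 7.0

    @given(a=st.floats(0, 1e5), b=st.floats(0, 1e5))
    def test_mean_bounded_by_arguments(self, a, b):
        m = combine_area(a, b)
        assert min(a, b) <= m <= max(a, b)

    def test_negative_refused(self):
        with pytest.raises(ValueError):
            combine_area(-1, 5)


class TestCountDispersedCells:
    def test_no_signal_counts_zero(self):
        assert count_dispersed_cells(np.zeros((100, 100)),
                                     YolkRoi((50, 50), (20, 20))) == 0

    def test_spots_outside_roi_counted(self):
        img = np.zeros((200, 200))
        roi = YolkRoi((50, 100), (30, 30))
        for y, x in [(20, 120), (20, 160), (70, 140), (110, 180),
                     (150, 120), (150, 170), (185, 150)]:
            rr, cc = draw_disk((y, x), 2.5, shape=img.shape)
            img[rr, cc] = 200.0
        assert count_dispersed_cells(img, roi) == 7

    def test_spot_below_min_area_excluded(self):
        img = np.zeros((100, 100))
        img[20, 80] = 200.0  # single pixel < min_spot_area
        rr, cc = draw_disk((70, 80), 3, shape=img.shape)
        img[rr, cc] = 200.0
        assert count_dispersed_cells(img, YolkRoi((30, 50), (20, 20))) == 1

    def test_component_touching_roi_not_dispersed(self):
        img = np.zeros((100, 100))
        rr, cc = draw_disk((50, 50), 5, shape=img.shape)
        img[rr, cc] = 200.0  # inside ROI -> tumor, not a dispersed cell
        assert count_dispersed_cells(img, YolkRoi((50, 50), (20, 20))) == 0


class TestClassifyEmbryo:
    @pytest.mark.parametrize("area, dispersed, expected", [
        (0, 0, (NO_CELLS, False)),
        (5000, 0, (LOCALIZED, False)),
        (5000, 4, (LOCALIZED, False)),   # below the 5-cell rule: negative
        (5000, 5, (INVADED, True)),      # minimum 5 cells scores positive
        (5000, 6, (INVADED, True)),
        (0, 3, (LOCALIZED, False)),      # some signal, sub-threshold
    ])
    def test_partition(self, area, dispersed, expected):
        assert classify_embryo(area, dispersed) == expected

    def test_threshold_configurable(self):
        cfg = MetastasisConfig(min_cells=10)
        assert classify_embryo(100, 6, cfg) == (LOCALIZED, False)
        assert classify_embryo(100, 10, cfg) == (INVADED, True)


def _group(cell_line, phenotype, n_no, n_loc, n_inv, n_pos_of_inv=None):
    out = []
    n_pos = n_inv if n_pos_of_inv is None else n_pos_of_inv
    for i in range(n_no):
        out.append(EmbryoPhenotype(f"{cell_line}{phenotype}no{i}", phenotype,
                                   cell_line, status=NO_CELLS))
    for i in range(n_loc):
        out.append(EmbryoPhenotype(f"{cell_line}{phenotype}loc{i}", phenotype,
                                   cell_line, tumor_area=500, status=LOCALIZED))
    for i in range(n_inv):
        out.append(EmbryoPhenotype(
            f"{cell_line}{phenotype}inv{i}", phenotype, cell_line,
            tumor_area=500, dispersed_cell_count=6, status=INVADED,
            metastasis_positive=i < n_pos))
    return out


class TestCohortTable:
    def test_published_cohort_tumorigenicity_percentages(self):
        """The four xenograft cohorts' printed category counts reproduce
        their printed tumorigenicity percentages exactly."""
        cohort = (_group("Hep3B", "-/-", 6, 26, 0)
                  + _group("Hep3B", "+/?", 12, 89, 10)
                  + _group("SKHep1", "-/-", 4, 20, 4)
                  + _group("SKHep1", "+/?", 0, 54, 20))
        table = cohort_table(cohort).set_index(["cell_line", "phenotype"])
        assert table.loc[("Hep3B", "-/-"), "n_total"] == 32
        assert table.loc[("Hep3B", "-/-"), "tumorigenicity_pct"] == 81.3
        assert table.loc[("Hep3B", "+/?"), "tumorigenicity_pct"] == 80.2
        assert table.loc[("SKHep1", "-/-"), "tumorigenicity_pct"] == 71.4
        assert table.loc[("SKHep1", "+/?"), "tumorigenicity_pct"] == 73.0

    def test_all_no_cells_group_is_zero_percent(self):
        table = cohort_table(_group("Hep3B", "-/-", 10, 0, 0))
        assert table.iloc[0].tumorigenicity_pct == 0.0

    def test_percentages_within_bounds_and_counts_sum(self):
        cohort = _group("X", "g", 3, 5, 2)
        row = cohort_table(cohort).iloc[0]
        assert row.n_no_cells + row.n_localized + row.n_invaded == row.n_total
        assert 0 <= row.tumorigenicity_pct <= 100
        assert 0 <= row.metastasis_pct <= 100

    def test_empty_metastasis_denominator_reported_absent(self):
        table = cohort_table(_group("X", "g", 4, 0, 0))
        assert math.isnan(table.iloc[0].metastasis_pct)

    def test_metastasis_denominator_configurable(self):
        cohort = _group("X", "g", 5, 3, 2)
        with_signal = cohort_table(cohort).iloc[0].metastasis_pct
        total = cohort_table(cohort, metastasis_denominator="total"
                             ).iloc[0].metastasis_pct
        assert with_signal == 40.0  # 2 / 5 with signal
        assert total == 20.0        # 2 / 10 injected

    def test_half_up_rounding_convention(self):
        # 5/8 = 62.5%, 3/8 = 37.5%: half-up keeps the terminal 5
        table = cohort_table(_group("X", "g", 3, 5, 0))
        assert table.iloc[0].tumorigenicity_pct == 62.5
        table2 = cohort_table(_group("X", "g", 563, 437, 0))
        assert table2.iloc[0].tumorigenicity_pct == 43.7
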