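"""Quantification: areas, aggregates, nucleus counts, foci, scores,
segregation, cell counts."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon
from skimage.draw import disk

import elsquant as e
from elsquant.quant import AggregateMetrics, detect_aggregates, count_nuclei


class TestAreas:
    def test_marker_area_basics(self):
        assert e.marker_area(np.zeros((5, 5), bool), 1.0) == 0.0
        m = np.zeros((40, 40), bool)
        m.ravel()[:1000] = True
        assert e.marker_area(m, 1.0) == pytest.approx(1000.0)

    def test_intersection_trivial_cases(self, rng):
        a = rng.random((32, 32)) < 0.3
        b = ~a
        assert e.intersection_area(a, b, 1.0) == 0.0
        assert e.intersection_area(a, a, 1.0) == e.marker_area(a, 1.0)

    def test_intersection_brute_force_and_polygon_agreement(self, rng):
        a = rng.random((64, 64)) < 0.35
        b = rng.random((64, 64)) < 0.35
        brute = float((a & b).sum()) * 1.3**2
        assert e.intersection_area(a, b, 1.3, "raster") == pytest.approx(brute)
        assert e.intersection_area(a, b, 1.3, "polygon") == pytest.approx(brute)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            e.intersection_area(np.zeros((2, 2), bool), np.zeros((3, 3), bool), 1.0)


class TestDetectAggregates:
    def test_planted_disjoint_aggregates_found(self, small_field, otsu_specs):
        img, truth = small_field
        t_spec, b_spec = otsu_specs
        mt = e.global_threshold(img, t_spec)
        mb = e.global_threshold(img, b_spec)
        fps = detect_aggregates(mt, mb, img.pixel_size_um, 500.0)
        assert len(fps) == len(truth.aggregates)

    def test_touching_subclusters_form_one_footprint(self):
        cfg = e.SimulationConfig(
            field_width_px=600, field_height_px=600, n_aggregates=1,
            nuclei_per_aggregate=80, segregation_mode="segregated",
            separation_factor=1.0,
        )
        img, _ = e.simulate_field(cfg, seed=4)
        mt = e.global_threshold(img, e.ThresholdSpec("CD3", method="otsu"))
        mb = e.global_threshold(img, e.ThresholdSpec("B220", method="otsu"))
        fps = detect_aggregates(mt, mb, img.pixel_size_um, 500.0)
        assert len(fps) == 1
        assert fps[0].t_mask.any() and fps[0].b_mask.any()

    def test_empty_masks_give_empty_list(self):
        z = np.zeros((16, 16), bool)
        assert detect_aggregates(z, z, 1.0) == []


class TestCountNuclei:
    @staticmethod
    def _whole_field_footprint(img):
        ones = np.ones(img.shape, dtype=bool)
        return detect_aggregates(ones, ones, img.pixel_size_um)[0]

    def test_empty_footprint_counts_zero(self):
        img = e.MultiplexImage({"DAPI": np.zeros((32, 32))}, 1.0)
        fp = self._whole_field_footprint(img)
        fp.mask[:] = False
        assert count_nuclei(img.channel("DAPI"), fp, 3.0, 1.0) == 0

    def test_well_separated_nuclei_counted_exactly(self):
        cfg = e.SimulationConfig(
            n_aggregates=1, nuclei_per_aggregate=60,
            nucleus_spacing_factor=3.0, segregation_mode="mixed",
            separation_factor=0.0,
        )
        for seed in range(3):
            img, _ = e.simulate_field(cfg, seed=seed)
            fp = self._whole_field_footprint(img)
            n = count_nuclei(img.channel("DAPI"), fp, 3.0, img.pixel_size_um)
            assert n == 60

    def test_dense_aggregate_within_fifteen_percent(self):
        cfg = e.SimulationConfig(n_aggregates=1, nuclei_per_aggregate=120)
        img, _ = e.simulate_field(cfg, seed=2)
        fp = self._whole_field_footprint(img)
        n = count_nuclei(img.channel("DAPI"), fp, 3.0, img.pixel_size_um)
        assert abs(n - 120) <= 0.15 * 120

    def test_area_ratio_method(self):
        cfg = e.SimulationConfig(n_aggregates=1, nuclei_per_aggregate=90)
        img, _ = e.simulate_field(cfg, seed=5)
        fp = self._whole_field_footprint(img)
        n = count_nuclei(
            img.channel("DAPI"), fp, 3.0, img.pixel_size_um, method="area_ratio"
        )
        assert abs(n - 90) <= 0.05 * 90

    def test_nonpositive_radius_rejected(self):
        img = e.MultiplexImage({"DAPI": np.zeros((8, 8))}, 1.0)
        fp = self._whole_field_footprint(img)
        with pytest.raises(ValueError, match="radius"):
            count_nuclei(img.channel("DAPI"), fp, 0.0, 1.0)


class TestFociAndScores:
    def test_focus_threshold_is_strict(self):
        assert e.detect_foci([50, 51, 200]) == [1, 2]
        assert e.detect_foci([]) == []
        assert e.detect_foci([50, 10, 3]) == []

    def test_focus_score_formula(self):
        assert e.focus_score(0, 5.0) == 0.0
        assert e.focus_score(4, 4.0) == pytest.approx(4.0)
        assert e.focus_score(3, 6.0) == pytest.approx(2.0)

    def test_focus_score_scale_invariance(self):
        assert e.focus_score(3, 6.0) == pytest.approx(e.focus_score(30, 60.0))

    def test_focus_score_invalid_area(self):
        with pytest.raises(ValueError):
            e.focus_score(1, 0.0)

    def test_aggregate_area_fraction(self):
        assert e.aggregate_area_fraction(0.0, 2.0) == 0.0
        assert e.aggregate_area_fraction(2.0, 2.0) == pytest.approx(100.0)
        assert e.aggregate_area_fraction(0.5, 2.0) == pytest.approx(25.0)

    def test_aggregate_exceeding_gland_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            e.aggregate_area_fraction(3.0, 2.0)


class TestGlandArea:
    def test_square_mask(self):
        m = np.ones((1000, 1000), bool)
        assert e.gland_area(m, 1.0) == pytest.approx(1.0)

    def test_simulated_gland_polygon_matches_truth_exactly(self):
        poly = Polygon([(50, 50), (450, 60), (430, 460), (60, 440)])
        cfg = e.SimulationConfig(
            field_width_px=512, field_height_px=512, gland_polygon=poly,
            n_aggregates=1, nuclei_per_aggregate=30,
        )
        _, truth = e.simulate_field(cfg, seed=1)
        assert e.gland_area(poly, cfg.pixel_size_um) == truth.gland_area_mm2

    def test_self_intersecting_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (10, 10), (10, 0), (0, 10)])
        with pytest.raises(ValueError, match="invalid"):
            e.gland_area(bowtie, 1.0)


class TestSegregation:
    def test_disjoint_areas_index_one(self):
        m = e.segregation_classify(
            AggregateMetrics(0, t_area_um2=100, b_area_um2=80,
                             intersection_area_um2=0, nucleus_count=60)
        )
        assert m.segregation_index == pytest.approx(1.0)
        assert m.segregated is True

    def test_identical_masks_index_zero(self):
        m = e.segregation_classify(
            AggregateMetrics(0, 100, 100, 100, 60)
        )
        assert m.segregation_index == pytest.approx(0.0)
        assert m.segregated is False

    def test_single_marker_aggregate_is_segregated(self):
        m = e.segregation_classify(AggregateMetrics(0, 100, 0, 0, 60))
        assert m.segregation_index == pytest.approx(1.0)
        assert m.segregated is True

    def test_undefined_when_both_zero_and_excluded_from_prevalence(self):
        undef = e.segregation_classify(AggregateMetrics(0, 0, 0, 0, 60))
        assert math.isnan(undef.segregation_index)
        assert undef.segregated is None
        seg = e.segregation_classify(AggregateMetrics(1, 10, 10, 0, 60))
        assert e.segregated_prevalence_pct([undef, seg]) == pytest.approx(100.0)
        assert math.isnan(e.segregated_prevalence_pct([undef]))

    def test_intersection_bound_enforced(self):
        with pytest.raises(ValueError, match="exceeds"):
            AggregateMetrics(0, 10, 10, 50, 5)


class TestFieldCellCounts:
    def test_worked_examples(self):
        a = np.ones((10, 10), bool)
        b = np.zeros((10, 10), bool)
        b[:, :4] = True
        pos = np.column_stack([np.arange(10), np.zeros(10)])  # row 0, cols 0..9
        fc = e.field_cell_counts(pos, a, b)
        assert fc.n_cells_marker_a == 10
        assert fc.n_cells_marker_a_and_b == 4
        assert fc.pct_double_positive == pytest.approx(40.0)

    def test_no_positive_cells_gives_missing_pct(self):
        z = np.zeros((5, 5), bool)
        fc = e.field_cell_counts(np.array([[1.0, 1.0]]), z, z)
        assert fc.pct_double_positive is None

    def test_recovers_planted_double_positive_fraction(self):
        """Paint a second marker over half the T cells of a simulated field;
        the double-positive percentage is recovered within 5 points."""
        cfg = e.SimulationConfig(n_aggregates=2, nuclei_per_aggregate=80,
                                 t_fraction=0.5)
        img, truth = e.simulate_field(cfg, seed=8)
        mt = e.global_threshold(img, e.ThresholdSpec("CD3", method="otsu"))
        centers, is_t = [], []
        for a in truth.aggregates:
            centers.append(a.nucleus_centers)
            is_t.append(a.nucleus_is_t)
        centers = np.concatenate(centers)
        is_t = np.concatenate(is_t)
        t_centers = centers[is_t]
        half = t_centers[: len(t_centers) // 2]
        painted = np.zeros(img.shape, bool)
        r_nuc = 3.0 / img.pixel_size_um  # nuclear co-stain footprint
        for x, y in half:
            rr, cc = disk((y, x), r_nuc, shape=painted.shape)
            painted[rr, cc] = True
        fc = e.field_cell_counts(t_centers, mt, painted)
        assert fc.pct_double_positive == pytest.approx(50.0, abs=5.0)


class TestQuantifyField:
    def test_summary_consistency(self, small_field, otsu_specs):
        img, truth = small_field
        gm = e.quantify_field(img, *otsu_specs)
        assert gm.focus_score == pytest.approx(gm.n_foci / gm.gland_area_mm2 * 4.0)
        assert gm.n_foci == truth.n_foci
        assert gm.aggregate_area_fraction_pct == pytest.approx(
            truth.true_aggregate_area_fraction_pct, rel=0.02
        )
        total_union = sum(
            m.t_area_um2 + m.b_area_um2 - m.intersection_area_um2
            for m in gm.aggregates
        )
        assert gm.aggregate_area_fraction_pct == pytest.approx(
            100.0 * total_union / 1e6 / gm.gland_area_mm2, rel=1e-9
        )
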