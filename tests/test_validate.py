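"""Buffered point-sampling validation, agreement statistics and density maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString, box

from hedgelines.errors import ParameterError, UndefinedStatisticError
from hedgelines.estimate import round_half_up
from hedgelines.network import BoundarySegment, LinearNetwork, assign_ids
from hedgelines.validate import (ConfusionMatrix, LabeledPoint,
                                 agreement_region, cohen_kappa, density_map,
                                 dominant_label, kappa_band, match_points,
                                 percent_agreement, sample_labeled_points)

# the published 2x2 point-match table the worked examples use
TABLE = ConfusionMatrix(n_ww=109_854, n_wo=80_623, n_ow=146_737, n_oo=288_115)


def net_of(lines, labels=None):
    segs = assign_ids([LineString(c) for c in lines])
    if labels:
        segs = [s.with_attrs(label=l) for s, l in zip(segs, labels)]
    return LinearNetwork(segs)


class TestDominantLabel:
    @pytest.mark.parametrize("classes,expected", [
        (["fence", "hedge"], "woody"),
        (["wall", "fence"], "other"),
        (["hedge"], "woody"),
    ])
    def test_woody_dominates_the_hierarchy(self, classes, expected):
        assert dominant_label(classes) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            dominant_label([])


class TestAgreementRegion:
    def test_identical_networks_give_own_buffer(self):
        net = net_of([[(0, 0), (100, 0)]])
        region = agreement_region(net, net, 5.0)
        buf = net.union().buffer(5.0)
        assert region.symmetric_difference(buf).area < 1e-9

    def test_far_apart_networks_give_empty_region(self):
        a = net_of([[(0, 0), (100, 0)]])
        b = net_of([[(0, 20), (100, 20)]])
        assert agreement_region(a, b, 5.0).is_empty

    def test_lens_area_matches_raster_oracle(self):
        # parallel 100-m lines 6 m apart with 5-m buffers: thin overlap lens
        a = net_of([[(0, 0), (100, 0)]])
        b = net_of([[(0, 6), (100, 6)]])
        region = agreement_region(a, b, 5.0)
        assert not region.is_empty
        # oracle: 0.1-m grid of cell centres, inside iff within 5 m of both lines
        step = 0.1
        xs = np.arange(-6, 106, step) + step / 2
        ys = np.arange(-5, 11, step) + step / 2
        X, Y = np.meshgrid(xs, ys)

        def dist_to_segment(X, Y, x1, y1, x2, y2):
            dx, dy = x2 - x1, y2 - y1
            t = np.clip(((X - x1) * dx + (Y - y1) * dy) / (dx * dx + dy * dy), 0, 1)
            return np.hypot(X - (x1 + t * dx), Y - (y1 + t * dy))

        inside = (dist_to_segment(X, Y, 0, 0, 100, 0) <= 5.0) & \
                 (dist_to_segment(X, Y, 0, 6, 100, 6) <= 5.0)
        oracle_area = inside.sum() * step * step
        assert region.area == pytest.approx(oracle_area, rel=0.01)

    def test_empty_network_is_not_an_error(self):
        assert agreement_region(LinearNetwork([]), net_of([[(0, 0), (1, 0)]])).is_empty

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ParameterError):
            agreement_region(LinearNetwork([]), LinearNetwork([]), 0.0)


class TestSampleLabeledPoints:
    def test_interval_arithmetic_on_contained_segment(self):
        net = net_of([[(10, 10), (30, 10)]], ["woody"])
        pts = sample_labeled_points(net, box(0, 0, 100, 100), interval=5.0)
        assert len(pts) == 5                       # 0, 5, 10, 15, 20 m
        assert {p.label for p in pts} == {1}
        assert pts[0].x == 10.0 and pts[-1].x == 30.0

    def test_segment_outside_region_gives_no_points(self):
        net = net_of([[(10, 50), (30, 50)]])
        assert sample_labeled_points(net, box(0, 0, 40, 40)) == []

    def test_partial_overlap_matches_rectangle_oracle(self):
        rect = box(0, 0, 17.0, 40.0)
        net = net_of([[(2, 20), (38, 20)]], ["other"])
        pts = sample_labeled_points(net, rect, interval=3.0)
        # oracle: enumerate arc-length multiples and test coordinates directly
        expected = []
        for k in range(13):
            d = min(3.0 * k, 36.0)
            x, y = 2 + d, 20.0
            if 0 <= x <= 17.0 and 0 <= y <= 40.0:
                expected.append((x, y))
        assert [(p.x, p.y) for p in pts] == expected

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ParameterError):
            sample_labeled_points(LinearNetwork([]), box(0, 0, 1, 1), 0.0)


def brute_force_match(model_pts, truth_pts, max_dist):
    cm = ConfusionMatrix()
    for t in truth_pts:
        best = None
        for i, m in enumerate(model_pts):
            d = np.hypot(m.x - t.x, m.y - t.y)
            if best is None or (d, i) < best[:2]:
                best = (d, i, m)
        if best is None or best[0] > max_dist:
            continue
        m = best[2]
        if m.label and t.label:
            cm.n_ww += 1
        elif m.label:
            cm.n_wo += 1
        elif t.label:
            cm.n_ow += 1
        else:
            cm.n_oo += 1
    return cm


class TestMatchPoints:
    def test_identical_point_sets_are_diagonal(self):
        pts = [LabeledPoint(float(i), 0.0, i % 2) for i in range(10)]
        cm = match_points(pts, pts, max_dist=0.5)
        assert cm.n_wo == cm.n_ow == 0
        assert cm.n_ww == 5 and cm.n_oo == 5

    def test_unmatched_truth_point_contributes_nothing(self):
        model = [LabeledPoint(0.0, 0.0, 1)]
        truth = [LabeledPoint(100.0, 0.0, 1)]
        assert match_points(model, truth, max_dist=10.0).total == 0

    def test_equals_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            model = [LabeledPoint(*rng.uniform(0, 50, 2), int(rng.integers(2)))
                     for _ in range(100)]
            truth = [LabeledPoint(*rng.uniform(0, 50, 2), int(rng.integers(2)))
                     for _ in range(100)]
            got = match_points(model, truth, max_dist=10.0)
            want = brute_force_match(model, truth, 10.0)
            assert got == want

    def test_direction_flag_swaps_roles(self):
        model = [LabeledPoint(0.0, 0.0, 1), LabeledPoint(10.0, 0.0, 0)]
        truth = [LabeledPoint(0.5, 0.0, 1)]
        fwd = match_points(model, truth, 5.0, "truth_to_model")
        rev = match_points(model, truth, 5.0, "model_to_truth")
        assert fwd.total == 1 and rev.total == 1
        assert fwd.n_ww == rev.n_ww == 1


class TestAgreementStatistics:
    def test_published_table_percent_agreement(self):
        assert round_half_up(percent_agreement(TABLE, "woody")) == 58
        assert round_half_up(percent_agreement(TABLE, "other")) == 66

    def test_empty_woody_row(self):
        cm = ConfusionMatrix(0, 0, 3, 7)
        assert percent_agreement(cm, "other") == pytest.approx(70.0)
        with pytest.raises(UndefinedStatisticError):
            percent_agreement(cm, "woody")

    def test_all_mismatch_row_is_zero(self):
        assert percent_agreement(ConfusionMatrix(0, 5, 0, 1), "woody") == 0.0

    def test_kappa_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix(10, 0, 0, 10)) == pytest.approx(1.0)

    def test_kappa_independent_classifiers(self):
        assert cohen_kappa(ConfusionMatrix(10, 10, 10, 10)) == pytest.approx(0.0)

    def test_kappa_published_table_matches_hand_calculation(self):
        from fractions import Fraction

        a, b, c, d = 109_854, 80_623, 146_737, 288_115
        n = a + b + c + d
        p_o = Fraction(a + d, n)
        p_e = (Fraction(a + b, n) * Fraction(a + c, n)
               + Fraction(c + d, n) * Fraction(b + d, n))
        expected = float((p_o - p_e) / (1 - p_e))
        assert cohen_kappa(TABLE) == pytest.approx(expected, abs=1e-12)

    def test_kappa_empty_matrix_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cohen_kappa(ConfusionMatrix())

    def test_degenerate_single_class_agreement(self):
        assert cohen_kappa(ConfusionMatrix(7, 0, 0, 0)) == 1.0
        assert cohen_kappa(ConfusionMatrix(5, 0, 3, 0)) == 0.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 1000)] * 4))
    def test_kappa_symmetric_under_label_swap(self, counts):
        a, b, c, d = counts
        if a + b + c + d == 0:
            return
        k1 = cohen_kappa(ConfusionMatrix(a, b, c, d))
        k2 = cohen_kappa(ConfusionMatrix(d, c, b, a))
        assert k1 == pytest.approx(k2, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(st.integers(1, 500), st.integers(0, 500),
                     st.integers(0, 500), st.integers(1, 500)))
    def test_kappa_is_one_iff_off_diagonal_empty(self, counts):
        a, b, c, d = counts
        k = cohen_kappa(ConfusionMatrix(a, b, c, d))
        assert (k == pytest.approx(1.0)) == (b == 0 and c == 0)

    def test_band_labels(self):
        assert kappa_band(0.3) == "fair"
        assert kappa_band(0.5) == "moderate"
        assert kappa_band(-0.2) == "poor"


class TestDensityMap:
    def test_empty_network_is_all_zero(self):
        d = density_map(LinearNetwork([]), 0, 2000, 2, 2)
        assert np.array_equal(d.values, np.zeros((2, 2)))

    def test_one_km_segment_in_one_cell(self):
        net = net_of([[(0, 500), (1000, 500)]], ["woody"])
        d = density_map(net, 0, 1000, 1, 1)
        assert d.values[0, 0] == pytest.approx(1000.0)    # m per km^2

    def test_diagonal_segment_split_matches_hand_clipping(self):
        # diagonal from (500,500) to (1500,1500) crosses the corner at (1000,1000)
        net = net_of([[(500, 500), (1500, 1500)]], ["woody"])
        d = density_map(net, 0, 2000, 2, 2)
        half = 500 * np.sqrt(2)
        assert d.values[1, 0] == pytest.approx(half)      # SW cell
        assert d.values[0, 1] == pytest.approx(half)      # NE cell
        assert d.values[0, 0] == 0.0 and d.values[1, 1] == 0.0

    def test_total_density_times_area_conserves_length(self, clean_land,
                                                       clean_masked):
        from hedgelines.classify import classify_network

        net = classify_network(clean_land.truth_network, clean_masked)
        n = int(clean_land.params.extent)
        d = density_map(net, 0, n * 1000.0, n, n)
        assert d.values.sum() * 1.0 == pytest.approx(net.woody_length(), abs=1e-6)
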