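"""Stratified expansion estimation and threshold calibration."""

import numpy as np
import pytest
from shapely.geometry import LineString, box

from hedgelines.classify import ThresholdSet
from hedgelines.errors import (CompletenessError, ParameterError,
                               SquareLookupError)
from hedgelines.estimate import (CalibrationSpec, StratumTable,
                                 calibrate_thresholds, length_ratio_report,
                                 make_square_grid, make_threshold_evaluator,
                                 per_square_woody_lengths, round_half_up,
                                 square_woody_length, stratified_total)
from hedgelines.network import BoundarySegment, LinearNetwork


def woody(coords, sq=None):
    return BoundarySegment(id=f"w{coords[0]}", geometry=LineString(coords),
                           label="woody", square_id=sq)


ONE_SQUARE = make_square_grid(0, 0, 1, 1)


class TestSquareWoodyLength:
    def test_square_without_woody_segments_is_zero(self):
        net = LinearNetwork([woody([(0, 10), (100, 10)]).with_attrs(label="other")])
        assert square_woody_length(net, "0_0", ONE_SQUARE) == 0.0

    def test_lengths_add(self):
        net = LinearNetwork([woody([(0, 10), (100, 10)]),
                             woody([(0, 20), (250, 20)])])
        assert square_woody_length(net, "0_0", ONE_SQUARE) == pytest.approx(350.0)

    def test_segment_clipped_at_square_border(self):
        # 300-m woody segment, half inside the square
        net = LinearNetwork([woody([(850.0, 500.0), (1150.0, 500.0)])])
        assert square_woody_length(net, "0_0", ONE_SQUARE) == pytest.approx(150.0)

    def test_unknown_square_id(self):
        with pytest.raises(SquareLookupError):
            square_woody_length(LinearNetwork([]), "9_9", ONE_SQUARE)

    def test_tagged_lookup_without_geometry(self):
        net = LinearNetwork([woody([(0, 10), (100, 10)], sq="3_4")])
        assert square_woody_length(net, "3_4") == pytest.approx(100.0)
        with pytest.raises(SquareLookupError):
            square_woody_length(net, "0_0")


class TestStratifiedTotal:
    def test_hand_arithmetic(self):
        strata = StratumTable([("lc1", 10, ["a", "b"])])
        total = stratified_total({"a": 1000.0, "b": 3000.0}, strata)
        assert total == pytest.approx(20.0)   # 10 squares x 2,000 m = 20 km

    def test_all_zero(self):
        strata = StratumTable([("lc1", 5, ["a"]), ("lc2", 7, ["b"])])
        assert stratified_total({"a": 0.0, "b": 0.0}, strata) == 0.0

    def test_missing_square_lists_ids(self):
        strata = StratumTable([("lc1", 2, ["a", "zz"])])
        with pytest.raises(CompletenessError, match="zz"):
            stratified_total({"a": 1.0}, strata)

    def test_census_limit_recovers_exact_total(self, clean_land, clean_masked):
        """Sampling every square makes the estimator exact."""
        from hedgelines.classify import classify_network

        net = classify_network(clean_land.truth_network, clean_masked)
        lengths = per_square_woody_lengths(net, clean_land.squares)
        total_km = stratified_total(lengths, clean_land.strata)
        assert total_km * 1000 == pytest.approx(net.woody_length(), abs=1e-6)

    def test_linear_and_order_invariant(self):
        rng = np.random.default_rng(2)
        lengths = {f"q{i}": float(v) for i, v in
                   enumerate(rng.uniform(0, 5000, 8))}
        rows = [("s1", 10, ["q0", "q1", "q2"]), ("s2", 4, ["q3", "q4"]),
                ("s3", 9, ["q5", "q6", "q7"])]
        t1 = stratified_total(lengths, StratumTable(rows))
        t2 = stratified_total(lengths, StratumTable(rows[::-1]))
        assert t1 == pytest.approx(t2)
        doubled = {k: 2 * v for k, v in lengths.items()}
        assert stratified_total(doubled, StratumTable(rows)) == pytest.approx(2 * t1)

    def test_unweighted_mode_sums_sample_lengths(self):
        strata = StratumTable([("lc1", 10, ["a", "b"])])
        total = stratified_total({"a": 1000.0, "b": 3000.0}, strata,
                                 weighted=False)
        assert total == pytest.approx(4.0)

    def test_table_validation(self):
        with pytest.raises(ParameterError):
            StratumTable([("a", 1, ["x", "y"])])      # pop < sampled
        with pytest.raises(ParameterError):
            StratumTable([("a", 1, [])])              # no samples
        with pytest.raises(ParameterError):
            StratumTable([("a", 1, ["x"]), ("a", 1, ["y"])])   # duplicate id

    def test_csv_round_trip(self, tmp_path):
        strata = StratumTable([("lc1", 10, ["a", "b"]), ("lc2", 3, ["c"])])
        path = tmp_path / "strata.csv"
        strata.to_csv(path)
        assert StratumTable.from_csv(path).rows == strata.rows


class TestCalibration:
    def fake_evaluator(self):
        """Four attributed segments of 1 km each in one square; the two
        hedges have mean heights 2.0 and 3.0, the others 0.2 and 0.3."""
        segs = []
        for i, mean in enumerate([0.2, 0.3, 2.0, 3.0]):
            segs.append(BoundarySegment(
                id=f"s{i}", geometry=LineString([(10, 100 + 100 * i),
                                                 (990, 100 + 100 * i)]),
                min_h=0.0, mean_h=mean, max_h=mean + 1.0))
        net = LinearNetwork(segs)
        strata = StratumTable([("all", 1, ["0_0"])])
        return make_threshold_evaluator(net, ONE_SQUARE, strata)

    def test_target_met_at_start_returns_start(self):
        evaluate = self.fake_evaluator()
        start = ThresholdSet(-0.13, 1.5, 58.0)
        spec = CalibrationSpec(target_total=evaluate(start))
        best, obj = calibrate_thresholds(evaluate, spec, start)
        assert best == start and obj == 0.0

    def test_recovers_separating_mean_within_one_step(self):
        evaluate = self.fake_evaluator()
        target = evaluate(ThresholdSet(-0.13, 1.0, 58.0))   # both hedges
        spec = CalibrationSpec(target_total=target,
                               ranges={"min_h_floor": (-1.0, 0.0),
                                       "mean_h_floor": (0.0, 5.0),
                                       "max_h_ceiling": (10.0, 60.0)})
        best, obj = calibrate_thresholds(evaluate, spec,
                                         ThresholdSet(-0.13, 2.5, 58.0))
        assert obj == 0.0
        assert best.mean_h_floor == pytest.approx(2.0, abs=0.01 + 1e-9)

    def test_infeasible_target_saturates_with_nonzero_objective(self):
        evaluate = self.fake_evaluator()
        max_total = evaluate(ThresholdSet(-1.0, 0.0, 60.0))
        spec = CalibrationSpec(target_total=10 * max_total + 5,
                               ranges={"min_h_floor": (-1.0, 0.0),
                                       "mean_h_floor": (0.0, 5.0),
                                       "max_h_ceiling": (10.0, 60.0)})
        best, obj = calibrate_thresholds(evaluate, spec,
                                         ThresholdSet(-0.13, 0.58, 58.0))
        assert obj > 0
        assert evaluate(best) == pytest.approx(max_total)  # fully permissive

    def test_never_worse_than_start(self):
        evaluate = self.fake_evaluator()
        rng = np.random.default_rng(4)
        for _ in range(5):
            start = ThresholdSet(-0.13, float(rng.uniform(0, 4)), 58.0)
            target = float(rng.uniform(0, 5))
            spec = CalibrationSpec(target_total=target,
                                   ranges={"min_h_floor": (-1.0, 0.0),
                                           "mean_h_floor": (0.0, 5.0),
                                           "max_h_ceiling": (10.0, 60.0)})
            _, obj = calibrate_thresholds(evaluate, spec, start)
            assert obj <= abs(evaluate(start) - target) + 1e-12

    def test_start_outside_ranges_rejected(self):
        spec = CalibrationSpec(target_total=1.0,
                               ranges={"min_h_floor": (-1.0, 0.0),
                                       "mean_h_floor": (0.0, 5.0),
                                       "max_h_ceiling": (10.0, 60.0)})
        with pytest.raises(ParameterError):
            calibrate_thresholds(lambda t: 0.0, spec, ThresholdSet(-2.0, 1.0, 58.0))

    def test_candidates_logged(self):
        evaluate = self.fake_evaluator()
        log = []
        spec = CalibrationSpec(target_total=0.0, max_sweeps=1,
                               ranges={"min_h_floor": (-0.2, -0.1),
                                       "mean_h_floor": (0.5, 0.7),
                                       "max_h_ceiling": (57.0, 59.0)})
        calibrate_thresholds(evaluate, spec, log=log)
        assert len(log) > 3 and all(len(rec) == 3 for rec in log)


class TestRatioReport:
    def test_model_versus_survey_percentages(self):
        # national totals in thousand km, model vs survey
        report = length_ratio_report({
            "Great Britain": (420.9, 700.0),
            "England": (333.0, 547.0),
            "Scotland": (34.0, 46.0),
            "Wales": (53.8, 106.0),
        }).set_index("region")
        assert report.loc["Great Britain", "ratio_pct"] == 60
        assert report.loc["Wales", "ratio_pct"] == 51
        assert report.loc["Great Britain", "shortfall_pct"] == 40

    def test_round_half_up(self):
        assert round_half_up(0.5) == 1
        assert round_half_up(60.13) == 60
        assert round_half_up(73.9) == 74
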