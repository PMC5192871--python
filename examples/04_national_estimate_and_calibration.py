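"""Stratified expansion to a national total, and threshold calibration.

Per-square woody lengths are expanded with the classical stratified
estimator (population squares x stratum sample mean).  The three
classification thresholds can then be calibrated: each is varied
sequentially in 0.01-m increments to match a survey length target.
"""

import hedgelines as hl
from hedgelines.classify import ThresholdSet, attribute_segment
from hedgelines.estimate import (CalibrationSpec, calibrate_thresholds,
                                 make_threshold_evaluator,
                                 per_square_woody_lengths, stratified_total)
from hedgelines.network import LinearNetwork

land = hl.generate_landscape(hl.LandscapeParams(
    extent=4, seed=20, noise_sd=0.0, tree_prob=0.0, ditch_prob=0.0,
    gap_fraction=0.2, woodland_frac=0.0, urban_frac=0.0))
chm = hl.canopy_height(land.dsm, land.dtm)
masked = hl.apply_mask(chm, land.landcover, land.dtm)

lengths = per_square_woody_lengths(land.truth_network, land.squares)
census = stratified_total(lengths, land.strata)
print(f"census stratified total: {census:.2f} km "
      f"(true total {land.true_woody_length()/1000:.2f} km)")

attributed = LinearNetwork([
    attribute_segment(s, masked).with_attrs(label=s.label)
    for s in land.truth_network.segments])
separating = min(s.mean_h for s in attributed if s.label == "woody")
evaluate = make_threshold_evaluator(attributed, land.squares, land.strata)
spec = CalibrationSpec(target_total=land.true_woody_length() / 1000.0,
                       ranges={"min_h_floor": (-1.0, 0.0),
                               "mean_h_floor": (0.0, 5.0),
                               "max_h_ceiling": (10.0, 60.0)})
best, objective = calibrate_thresholds(evaluate, spec,
                                       ThresholdSet(-0.13, 2.5, 58.0))
print(f"calibrated mean-height floor: {best.mean_h_floor:.2f} m "
      f"(smallest hedge mean {separating:.3f} m), objective {objective:.3f} km")
print()
print("Calibration recovers the height value that separates hedge")
print("boundaries from the rest to within one 0.01-m increment.")
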