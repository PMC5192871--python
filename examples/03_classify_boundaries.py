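"""Classify boundary segments as woody or other by the height thresholds.

Generates a small synthetic landscape with known hedges, attributes each
boundary with min/mean/max canopy height sampled every 5 m along it, and
applies the three-threshold rule: minimum >= -0.13 m (ditch tolerance),
mean >= 0.58 m (gappy hedges), maximum <= 58 m (tallest tree in GB).
"""

import hedgelines as hl

land = hl.generate_landscape(hl.LandscapeParams(extent=2, seed=5))
chm = hl.canopy_height(land.dsm, land.dtm)
masked = hl.apply_mask(chm, land.landcover, land.dtm)
classified = hl.classify_network(land.truth_network, masked)

true_w = {s.id for s in land.truth_network if s.label == "woody"}
pred_w = {s.id for s in classified if s.label == "woody"}
print(f"boundaries: {len(classified)}; true hedges: {len(true_w)}")
print(f"detected as woody: {len(pred_w)} "
      f"(hits {len(true_w & pred_w)}, false positives {len(pred_w - true_w)})")
print(f"woody length: modelled {classified.woody_length()/1000:.2f} km, "
      f"true {land.true_woody_length()/1000:.2f} km")

example = next(s for s in classified if s.label == "woody")
print(f"example woody segment {example.id}: min {example.min_h:.2f} m, "
      f"mean {example.mean_h:.2f} m, max {example.max_h:.2f} m")
print()
print("Under the default noisy, gappy conditions the model under-detects")
print("slightly, and errors are omissions rather than false hedges - the")
print("same asymmetry seen when the method is applied to real survey data.")
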