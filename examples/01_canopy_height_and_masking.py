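"""Canopy height from paired surface/terrain grids, then screening.

Builds a tiny 4x4 grid pair by hand, differences them into a canopy height
model (CHM), and zeroes the areas where woody linear features cannot occur
or be detected: woodland/built-up land cover and ground above 300 m.
"""

import numpy as np

from hedgelines import HeightGrid, LandCoverGrid, MaskConfig, apply_mask, canopy_height

dtm = HeightGrid(0, 20, 5.0, np.array([
    [100.0, 100.0, 100.0, 310.0],
    [100.0, 100.0, 100.0, 310.0],
    [100.0, 100.0, 100.0, 100.0],
    [100.0, 100.0, 100.0, 100.0],
]))
# the surface sits 2.5 m above ground along a hedge row, 15 m over a wood
dsm = HeightGrid(0, 20, 5.0, dtm.values + np.array([
    [0.0, 2.5, 2.5, 2.5],
    [0.0, 0.0, 0.0, 0.0],
    [15.0, 15.0, 0.0, 0.0],
    [15.0, 15.0, 0.0, 0.0],
]))
landcover = LandCoverGrid(0, 20, 5.0, np.array([
    [0, 0, 0, 0],
    [0, 0, 0, 0],
    [2, 2, 0, 0],
    [2, 2, 0, 0],
]), legend={0: "other", 1: "built_up", 2: "woodland", 3: "littoral",
            4: "sublittoral"})

chm = canopy_height(dsm, dtm)
masked = apply_mask(chm, landcover, dtm, MaskConfig())

print("canopy height model (m):")
print(chm.values)
print("after masking woodland and >300 m ground (m):")
print(masked.values)
print()
print("The 2.5-m hedge canopy survives except where the ground is above the")
print("300-m altitude cutoff; the 15-m woodland canopy is zeroed because")
print("closed woodland would otherwise read as one giant woody feature.")
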