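"""One reproducible end-to-end run from files on disk.

Writes a synthetic landscape bundle (ASCII grids, GeoJSON, CSV), then runs
mask -> network -> classify -> estimate -> validate through the pipeline
driver, which also emits a manifest recording the configuration hash.
"""

import json
import tempfile
from pathlib import Path

import hedgelines as hl

work = Path(tempfile.mkdtemp())
land = hl.generate_landscape(hl.LandscapeParams(extent=2, seed=5))
paths = hl.write_landscape(land, work / "land")

cfg = hl.RunConfig(
    dtm_path=paths["dtm"], dsm_path=paths["dsm"],
    landcover_path=paths["landcover"], legend_path=paths["legend"],
    polygons_path=paths["polygons"], truth_path=paths["truth"],
    strata_path=paths["strata"], out_dir=str(work / "out"),
)
results = hl.run_pipeline(cfg)

print(f"stratified woody total: {results['total_woody_km']:.2f} km "
      f"(true {land.true_woody_length()/1000:.2f} km)")
v = results["validation"]
print(f"validation vs reference: kappa {v['kappa']:.3f} ({v['kappa_band']}), "
      f"woody-row agreement {v['woody_agreement_pct']:.0f}%")
manifest = json.load(open(results["outputs"]["manifest"]))
print(f"outputs under {cfg.out_dir}; manifest hash {manifest['config_hash'][:12]}…")
print()
print("Rerunning with the same inputs and configuration reproduces every")
print("output byte for byte; the manifest makes the run auditable.")
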