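"""End-to-end orchestration: mask -> network -> classify -> estimate -> validate.

A run is a pure function of (inputs, configuration, seed).  Alongside its
outputs it writes a machine-readable manifest recording the configuration
hash, package version and seed, so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from . import __version__
from .classify import ThresholdSet, classify_network
from .errors import ConfigurationError, ParameterError
from .estimate import (StratumTable, make_square_grid, per_square_woody_lengths,
                       per_stratum_table, stratified_total)
from .grids import HeightGrid, LandCoverGrid, MaskConfig, apply_mask, canopy_height
from .network import (LinearNetwork, generalize, polygons_to_network,
                      read_network, read_polygons, split_segments, write_network)
from .raster_io import (as_landcover, read_ascii_grid, read_geotiff, read_legend,
                        write_ascii_grid)
from .validate import (agreement_region, cohen_kappa, kappa_band, match_points,
                       percent_agreement, sample_labeled_points, density_map)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    dtm_path: str = ""
    dsm_path: str = ""
    landcover_path: str = ""
    legend_path: str = ""
    terrain_path: str = ""          # altitude screen; defaults to the DTM
    polygons_path: str = ""         # either a polygon mosaic ...
    network_path: str = ""          # ... or a pre-built line network
    truth_path: str = ""            # optional reference network
    strata_path: str = ""           # optional stratum table CSV
    out_dir: str = "out"

    min_h_floor: float = -0.13
    mean_h_floor: float = 0.58
    max_h_ceiling: float = 58.0
    altitude_cutoff: float = 300.0
    generalize_tolerance: float = 0.0
    sample_step: float | None = None
    buffer_radius: float = 5.0
    point_interval: float = 5.0
    max_dist: float = 10.0
    square_size: float = 1000.0
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        """Reject out-of-range parameters before any compute."""
        if self.buffer_radius <= 0:
            raise ParameterError("buffer_radius must be > 0")
        if self.point_interval <= 0:
            raise ParameterError("point_interval must be > 0")
        if self.max_dist <= 0:
            raise ParameterError("max_dist must be > 0")
        if self.square_size <= 0:
            raise ParameterError("square_size must be > 0")
        if self.generalize_tolerance < 0:
            raise ParameterError("generalize_tolerance must be >= 0")
        if self.sample_step is not None and self.sample_step <= 0:
            raise ParameterError("sample_step must be > 0")
        ThresholdSet(self.min_h_floor, self.mean_h_floor, self.max_h_ceiling)
        if not (self.polygons_path or self.network_path):
            raise ConfigurationError("either polygons_path or network_path is required")
        for name in ("dtm_path", "dsm_path", "landcover_path"):
            if not getattr(self, name):
                raise ConfigurationError(f"{name} is required")

    def thresholds(self) -> ThresholdSet:
        return ThresholdSet(self.min_h_floor, self.mean_h_floor, self.max_h_ceiling)

    def mask_config(self) -> MaskConfig:
        return MaskConfig(altitude_cutoff=self.altitude_cutoff)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_toml(cls, path: str, **overrides) -> "RunConfig":
        """Load a key-value TOML config; keyword overrides win on conflict."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _read_raster(path: str) -> HeightGrid:
    if path.endswith((".tif", ".tiff")):
        return read_geotiff(path)
    return read_ascii_grid(path)


def _default_legend(values: np.ndarray) -> dict[int, str]:
    # a bare numeric landcover raster with no legend: map codes positionally
    base = {0: "other", 1: "built_up", 2: "woodland", 3: "littoral", 4: "sublittoral"}
    legend = dict(base)
    for code in np.unique(values).astype(int):
        legend.setdefault(int(code), "other")
    return legend


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write all outputs under ``cfg.out_dir``.

    Any stage failure propagates with the stage context; nothing is
    computed until the configuration validates.
    """
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)

    # --- rasters: CHM and screening
    dtm = _read_raster(cfg.dtm_path)
    dsm = _read_raster(cfg.dsm_path)
    lc_raw = _read_raster(cfg.landcover_path)
    legend = (read_legend(cfg.legend_path) if cfg.legend_path
              else _default_legend(lc_raw.values))
    landcover = as_landcover(lc_raw, legend)
    terrain = _read_raster(cfg.terrain_path) if cfg.terrain_path else dtm
    chm = canopy_height(dsm, dtm)
    masked = apply_mask(chm, landcover, terrain, cfg.mask_config())

    # --- linear framework
    if cfg.network_path:
        net = read_network(cfg.network_path)
    else:
        net = polygons_to_network(read_polygons(cfg.polygons_path))
    net = generalize(net, cfg.generalize_tolerance)
    net = split_segments(net)

    # --- classification
    classified = classify_network(net, masked, cfg.thresholds(), cfg.sample_step)
    classified_path = os.path.join(cfg.out_dir, "classified.geojson")
    write_network(classified, classified_path)

    # --- stratified estimate
    x0, y_min, x_max, y0 = masked.bounds
    n_x = int(np.ceil((x_max - x0) / cfg.square_size))
    n_y = int(np.ceil((y0 - y_min) / cfg.square_size))
    squares = make_square_grid(x0, y_min, n_x, n_y, cfg.square_size)
    lengths = per_square_woody_lengths(classified, squares)
    if cfg.strata_path:
        strata = StratumTable.from_csv(cfg.strata_path)
    else:
        strata = StratumTable([("all", len(squares), sorted(squares))])
    table = per_stratum_table(lengths, strata)
    total_km = stratified_total(lengths, strata)
    estimates_path = os.path.join(cfg.out_dir, "estimates.csv")
    table.to_csv(estimates_path, index=False, float_format="%.6f")

    results: dict[str, Any] = {
        "classified": classified,
        "total_woody_km": total_km,
        "per_stratum": table,
        "outputs": {"classified": classified_path, "estimates": estimates_path},
    }

    # --- density map
    density = density_map(classified, x0, y0, n_x, n_y, cfg.square_size)
    density_path = os.path.join(cfg.out_dir, "density.asc")
    write_ascii_grid(density, density_path)
    results["outputs"]["density"] = density_path

    # --- validation against a reference network
    if cfg.truth_path:
        truth = read_network(cfg.truth_path)
        region = agreement_region(classified, truth, cfg.buffer_radius)
        model_pts = sample_labeled_points(classified, region, cfg.point_interval,
                                          source="model")
        truth_pts = sample_labeled_points(truth, region, cfg.point_interval,
                                          source="truth")
        cm = match_points(model_pts, truth_pts, cfg.max_dist)
        report = {
            "n_ww": cm.n_ww, "n_wo": cm.n_wo, "n_ow": cm.n_ow, "n_oo": cm.n_oo,
        }
        if cm.n_ww + cm.n_wo > 0:
            report["woody_agreement_pct"] = percent_agreement(cm, "woody")
        if cm.n_ow + cm.n_oo > 0:
            report["other_agreement_pct"] = percent_agreement(cm, "other")
        if cm.total > 0:
            report["kappa"] = cohen_kappa(cm)
            report["kappa_band"] = kappa_band(report["kappa"])
        cm_path = os.path.join(cfg.out_dir, "confusion.csv")
        with open(cm_path, "w") as fh:
            fh.write("model\\truth,woody,other\n")
            fh.write(f"woody,{cm.n_ww},{cm.n_wo}\n")
            fh.write(f"other,{cm.n_ow},{cm.n_oo}\n")
        summary_path = os.path.join(cfg.out_dir, "validation.json")
        with open(summary_path, "w") as fh:
            json.dump(report, fh, indent=1)
        results["confusion"] = cm
        results["validation"] = report
        results["outputs"]["confusion"] = cm_path
        results["outputs"]["validation"] = summary_path

    # --- manifest
    manifest = {
        "package": "hedgelines",
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "outputs": results["outputs"],
        "total_woody_km": total_km,
    }
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["outputs"]["manifest"] = manifest_path
    results["manifest"] = manifest
    return results
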