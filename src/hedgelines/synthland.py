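"""Seeded synthetic landscapes with known ground truth.

The generator emulates the data regime the pipeline consumes nationally: a
field mosaic whose shared boundaries form the linear framework, a smooth
terrain surface (DTM), a surface model (DSM) equal to the terrain plus a
painted canopy — hedges of 1–4 m on a known subset of boundaries, gaps,
occasional emergent trees, shallow ditch depressions beside hedges, and
optional surface noise — a categorical land-cover grid with woodland and
built-up patches, and a land-class stratification of the 1-km squares.

Everything derives from one ``numpy`` Generator seeded explicitly; the
draw order is fixed (node jitter, land-cover patches, hedge designation,
terrain phases, hedge heights, gap draws, tree draws, tree heights, ditch
draws, noise) so identical parameters and seed give bit-identical outputs,
and varying only a downstream parameter (e.g. ``gap_fraction``) leaves all
earlier draws — and therefore the landscape itself — unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from shapely.geometry import LineString, Polygon, box
from shapely.strtree import STRtree

from .errors import ParameterError
from .estimate import StratumTable, make_square_grid
from .grids import HeightGrid, LandCoverGrid
from .network import BoundarySegment, LinearNetwork, polygons_to_network

__all__ = ["LandscapeParams", "SyntheticLandscape", "generate_landscape",
           "degrade_truth", "LEGEND"]

LEGEND: dict[int, str] = {0: "other", 1: "built_up", 2: "woodland",
                          3: "littoral", 4: "sublittoral"}


@dataclass
class LandscapeParams:
    """Knobs of the synthetic landscape (lengths in metres unless noted)."""

    extent: int = 5                      # km, side of the square landscape
    field_scale: float = 200.0           # mean field edge
    hedge_prob_by_stratum: Mapping[str, float] | None = None
    hedge_height_range: tuple[float, float] = (1.0, 4.0)
    gap_fraction: float = 0.15           # share of hedge cells with no canopy
    tree_prob: float = 0.02              # emergent tree per hedge cell
    tree_height_max: float = 25.0
    ditch_prob: float = 0.10             # ditch cell beside a hedge
    ditch_depth: float = 0.10            # m below ground
    woodland_frac: float = 0.08          # area fraction
    urban_frac: float = 0.04
    terrain_relief: float = 60.0         # range of the smooth DTM
    noise_sd: float = 0.05               # white surface noise on the DSM; kept
                                         # small because real surface-model
                                         # error is spatially correlated and
                                         # independent per-cell noise is the
                                         # worst case for the min statistic
    cell_size: float = 5.0               # raster resolution
    hedge_width: float = 5.0             # painted canopy width
    n_strata: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hedge_prob_by_stratum is None:
            probs = np.linspace(0.6, 0.3, max(1, self.n_strata))
            self.hedge_prob_by_stratum = {
                str(i + 1): float(p) for i, p in enumerate(probs)
            }
        if self.extent < 1 or int(self.extent) != self.extent:
            raise ParameterError("extent must be a whole number of km >= 1")
        lo, hi = self.hedge_height_range
        if not (hi > lo >= 0):
            raise ParameterError("hedge_height_range must satisfy hi > lo >= 0")
        for name in ("gap_fraction", "tree_prob", "ditch_prob",
                     "woodland_frac", "urban_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        for p in self.hedge_prob_by_stratum.values():
            if not (0 <= p <= 1):
                raise ParameterError("hedge probabilities must lie in [0, 1]")
        if self.cell_size <= 0 or self.field_scale <= 0 or self.hedge_width <= 0:
            raise ParameterError("cell_size, field_scale, hedge_width must be > 0")
        if self.noise_sd < 0 or self.ditch_depth < 0 or self.terrain_relief < 0:
            raise ParameterError("noise_sd, ditch_depth, terrain_relief must be >= 0")


@dataclass
class SyntheticLandscape:
    """A generated world plus its ground truth."""

    params: LandscapeParams
    polygons: list[Polygon]
    truth_network: LinearNetwork
    dtm: HeightGrid
    dsm: HeightGrid
    landcover: LandCoverGrid
    strata: StratumTable
    squares: dict[str, Polygon]
    square_strata: dict[str, str]

    def true_woody_length(self) -> float:
        return self.truth_network.woody_length()


def _paint_rect(code_grid: np.ndarray, extent_m: float, cell: float,
                cx: float, cy: float, w: float, h: float, code: int) -> None:
    n = code_grid.shape[0]
    # cell (r, c) centre: x = (c+0.5)*cell, y = extent - (r+0.5)*cell
    c0 = max(0, int(np.floor((cx - w / 2) / cell)))
    c1 = min(n - 1, int(np.floor((cx + w / 2) / cell)))
    r0 = max(0, int(np.floor((extent_m - (cy + h / 2)) / cell)))
    r1 = min(n - 1, int(np.floor((extent_m - (cy - h / 2)) / cell)))
    if c1 >= c0 and r1 >= r0:
        code_grid[r0:r1 + 1, c0:c1 + 1] = code


def _paint_patches(rng, code_grid, extent_m, cell, frac, size_range, code):
    """Greedily add random rectangles until the area fraction is reached."""
    rects = []
    target = frac * code_grid.size
    guard = 0
    while np.count_nonzero(code_grid == code) < target and guard < 1000:
        guard += 1
        cx, cy = rng.uniform(0, extent_m, 2)
        w, h = rng.uniform(*size_range, 2)
        _paint_rect(code_grid, extent_m, cell, cx, cy, w, h, code)
        rects.append(box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2))
    return rects


def _segment_distance_field(canopy_shape, cell, extent_m, line: LineString,
                            reach: float):
    """(rows, cols, distances) of cells whose centre is within ``reach`` of a
    2-point line segment, computed with plain point-segment algebra."""
    (x1, y1), (x2, y2) = line.coords[0], line.coords[-1]
    n = canopy_shape[0]
    xmin, xmax = min(x1, x2) - reach, max(x1, x2) + reach
    ymin, ymax = min(y1, y2) - reach, max(y1, y2) + reach
    c0 = max(0, int(np.floor(xmin / cell)))
    c1 = min(n - 1, int(np.floor(xmax / cell)))
    r0 = max(0, int(np.floor((extent_m - ymax) / cell)))
    r1 = min(n - 1, int(np.floor((extent_m - ymin) / cell)))
    if c1 < c0 or r1 < r0:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    X = (cols[None, :] + 0.5) * cell
    Y = extent_m - (rows[:, None] + 0.5) * cell
    dx, dy = x2 - x1, y2 - y1
    L2 = dx * dx + dy * dy
    t = ((X - x1) * dx + (Y - y1) * dy) / L2 if L2 > 0 else np.zeros_like(X + Y)
    t = np.clip(t, 0.0, 1.0)
    px, py = x1 + t * dx, y1 + t * dy
    dist = np.hypot(X - px, Y - py)
    R, C = np.meshgrid(rows, cols, indexing="ij")
    keep = dist <= reach
    return R[keep], C[keep], dist[keep]


def generate_landscape(params: LandscapeParams | None = None
                       ) -> SyntheticLandscape:
    """Build a complete synthetic world from one seeded random stream."""
    p = params or LandscapeParams()
    rng = np.random.default_rng(p.seed)
    E = float(p.extent) * 1000.0
    cell = p.cell_size
    n_cells = int(round(E / cell))

    # 1. field mosaic: perturbed grid tessellation
    n_f = max(1, int(round(E / p.field_scale)))
    f = E / n_f
    gx, gy = np.meshgrid(np.arange(n_f + 1) * f, np.arange(n_f + 1) * f,
                         indexing="ij")
    jitter = rng.uniform(-0.2 * f, 0.2 * f, size=(n_f + 1, n_f + 1, 2))
    jitter[0, :, :] = jitter[-1, :, :] = 0.0
    jitter[:, 0, :] = jitter[:, -1, :] = 0.0
    nx = gx + jitter[:, :, 0]
    ny = gy + jitter[:, :, 1]
    polygons = [
        Polygon([(nx[i, j], ny[i, j]), (nx[i + 1, j], ny[i + 1, j]),
                 (nx[i + 1, j + 1], ny[i + 1, j + 1]), (nx[i, j + 1], ny[i, j + 1])])
        for i in range(n_f) for j in range(n_f)
    ]

    # 2. land cover patches (painted before hedges are designated, so that
    #    hedge placement can avoid them the way rural hedges avoid woods)
    codes = np.zeros((n_cells, n_cells), dtype=int)
    wood_rects = _paint_patches(rng, codes, E, cell, p.woodland_frac,
                                (200.0, 600.0), 2)
    urban_rects = _paint_patches(rng, codes, E, cell, p.urban_frac,
                                 (150.0, 400.0), 1)
    patches = wood_rects + urban_rects
    landcover = LandCoverGrid(0.0, E, cell, codes, LEGEND)

    # 3. boundary network and 1-km squares
    net = polygons_to_network(polygons)
    n_sq = int(p.extent)
    squares = make_square_grid(0.0, 0.0, n_sq, n_sq)
    square_strata = {
        f"{i}_{j}": str(1 + (j * p.n_strata) // n_sq) if p.n_strata > 1 else "1"
        for i in range(n_sq) for j in range(n_sq)
    }
    strata_rows: dict[str, list[str]] = {}
    for sq_id in sorted(squares):
        strata_rows.setdefault(square_strata[sq_id], []).append(sq_id)
    strata = StratumTable([
        (sid, len(ids), ids) for sid, ids in sorted(strata_rows.items())
    ])

    # 4. hedge designation (segments in deterministic id order)
    u = rng.uniform(size=len(net.segments))
    patch_tree = STRtree(patches) if patches else None
    segments: list[BoundarySegment] = []
    for seg, ui in zip(net.segments, u):
        mid = seg.geometry.interpolate(0.5, normalized=True)
        i = min(n_sq - 1, max(0, int(mid.x // 1000)))
        j = min(n_sq - 1, max(0, int(mid.y // 1000)))
        prob = p.hedge_prob_by_stratum.get(square_strata[f"{i}_{j}"], 0.0)
        in_patch = False
        if patch_tree is not None:
            in_patch = bool(len(patch_tree.query(seg.geometry,
                                                 predicate="intersects")))
        label = "woody" if (ui < prob and not in_patch) else "other"
        segments.append(seg.with_attrs(label=label, square_id=f"{i}_{j}"))
    truth = LinearNetwork(segments)

    # 5. smooth terrain
    phases = rng.uniform(0, 2 * np.pi, size=4)
    cx = (np.arange(n_cells) + 0.5) * cell
    cy = E - (np.arange(n_cells) + 0.5) * cell
    X, Y = np.meshgrid(cx, cy)
    g = (np.sin(2 * np.pi * X / E + phases[0]) * np.sin(2 * np.pi * Y / E + phases[1])
         + 0.5 * np.sin(4 * np.pi * X / E + phases[2])
         * np.sin(4 * np.pi * Y / E + phases[3]))
    if g.max() > g.min():
        g = (g - g.min()) / (g.max() - g.min())
    dtm_vals = 50.0 + p.terrain_relief * g
    dtm = HeightGrid(0.0, E, cell, dtm_vals)

    # 6. canopy: woodland/urban structure first, hedge canopy on top
    canopy = np.zeros((n_cells, n_cells))
    wood_mask = codes == 2
    urban_mask = codes == 1
    canopy[wood_mask] = rng.uniform(8.0, 25.0, int(wood_mask.sum()))
    canopy[urban_mask] = rng.uniform(4.0, 10.0, int(urban_mask.sum()))

    hedge_mask = np.zeros((n_cells, n_cells), dtype=bool)
    band_mask = np.zeros((n_cells, n_cells), dtype=bool)
    half_w = p.hedge_width / 2.0
    reach = half_w + cell
    for seg in truth.segments:
        if seg.label != "woody":
            continue
        R, C, D = _segment_distance_field((n_cells, n_cells), cell, E,
                                          seg.geometry, reach)
        hedge_mask[R[D <= half_w], C[D <= half_w]] = True
        inner = (D > half_w) & (D <= half_w + cell)
        band_mask[R[inner], C[inner]] = True
    band_mask &= ~hedge_mask

    hr, hc = np.nonzero(hedge_mask)           # row-major deterministic order
    n_h = hr.size
    lo, hi = p.hedge_height_range
    heights = rng.uniform(lo, hi, n_h)
    gap_u = rng.uniform(size=n_h)
    tree_u = rng.uniform(size=n_h)
    tree_h = rng.uniform(hi, max(hi + 1e-9, p.tree_height_max), n_h)
    heights = np.where(tree_u < p.tree_prob, tree_h, heights)
    heights = np.where(gap_u < p.gap_fraction, 0.0, heights)
    canopy[hr, hc] = heights

    br, bc = np.nonzero(band_mask)
    ditch_u = rng.uniform(size=br.size)
    hit = ditch_u < p.ditch_prob
    canopy[br[hit], bc[hit]] = -p.ditch_depth

    dsm_vals = dtm_vals + canopy
    if p.noise_sd > 0:
        dsm_vals = dsm_vals + rng.normal(0.0, p.noise_sd, dsm_vals.shape)
    dsm = HeightGrid(0.0, E, cell, dsm_vals)

    return SyntheticLandscape(p, polygons, truth, dtm, dsm, landcover, strata,
                              squares, square_strata)


def write_landscape(landscape: SyntheticLandscape, out_dir, fmt: str = "asc"
                    ) -> dict[str, str]:
    """Write a landscape to disk (rasters as .asc or .tif, vectors as
    GeoJSON, strata as CSV).  Returns the paths keyed by role."""
    import os

    from . import raster_io
    from .network import write_network, write_polygons

    os.makedirs(out_dir, exist_ok=True)
    if fmt not in {"asc", "tif"}:
        raise ParameterError(f"fmt must be 'asc' or 'tif', got {fmt!r}")
    write_raster = (raster_io.write_ascii_grid if fmt == "asc"
                    else raster_io.write_geotiff)
    paths = {
        "dtm": os.path.join(out_dir, f"dtm.{fmt}"),
        "dsm": os.path.join(out_dir, f"dsm.{fmt}"),
        "landcover": os.path.join(out_dir, f"landcover.{fmt}"),
        "legend": os.path.join(out_dir, "legend.csv"),
        "polygons": os.path.join(out_dir, "polygons.geojson"),
        "truth": os.path.join(out_dir, "truth.geojson"),
        "strata": os.path.join(out_dir, "strata.csv"),
    }
    write_raster(landscape.dtm, paths["dtm"])
    write_raster(landscape.dsm, paths["dsm"])
    write_raster(landscape.landcover, paths["landcover"])
    raster_io.write_legend(landscape.landcover.legend, paths["legend"])
    write_polygons(landscape.polygons, paths["polygons"])
    write_network(landscape.truth_network, paths["truth"])
    landscape.strata.to_csv(paths["strata"])
    return paths


def degrade_truth(truth_network: LinearNetwork, drop_prob: float = 0.0,
                  jitter_sd: float = 0.0, seed: int = 0) -> LinearNetwork:
    """Mimic independently derived linework: drop whole features with
    probability ``drop_prob`` and jitter every vertex with isotropic
    Gaussian noise of ``jitter_sd`` metres."""
    if not (0 <= drop_prob <= 1):
        raise ParameterError("drop_prob must lie in [0, 1]")
    if jitter_sd < 0:
        raise ParameterError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    keep_u = rng.uniform(size=len(truth_network.segments))
    out = []
    for seg, ku in zip(truth_network.segments, keep_u):
        if ku < drop_prob:
            continue
        coords = np.asarray(seg.geometry.coords, dtype=float)
        if jitter_sd > 0:
            coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
        out.append(replace(seg, geometry=LineString(coords)))
    return LinearNetwork(out, truth_network.crs_note)
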