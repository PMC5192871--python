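"""Spatial accuracy assessment of a modelled boundary classification.

The evaluation mirrors how a modelled network is compared against an
independently mapped reference ("survey") network whose linework does not
perfectly coincide with it: both networks are buffered by 5 m and only the
intersection of the buffers is compared; points are dropped every 5 m along
each network's segments inside that region, labelled woody (1) or other
(0); reference points are matched to their nearest model point; and the
resulting 2x2 confusion matrix yields per-class percent agreement and
Cohen's chance-corrected kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.prepared import prep

from .errors import ParameterError, UndefinedStatisticError
from .grids import HeightGrid
from .network import LinearNetwork

__all__ = [
    "LabeledPoint", "ConfusionMatrix", "dominant_label", "agreement_region",
    "sample_labeled_points", "match_points", "percent_agreement",
    "cohen_kappa", "kappa_band", "density_map", "stratum_mean_density",
]

#: survey feature classes treated as woody under the dominance rule
DEFAULT_WOODY_CLASSES = frozenset({"woody", "hedge", "line of trees", "shrub"})


@dataclass(frozen=True)
class LabeledPoint:
    x: float
    y: float
    label: int          # woody = 1, other = 0
    source: str = ""    # "model" or "truth"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ParameterError(f"label must be 0 or 1, got {self.label}")


@dataclass
class ConfusionMatrix:
    """2x2 point-match counts, model class (rows) x truth class (columns)."""

    n_ww: int = 0   # model woody, truth woody
    n_wo: int = 0   # model woody, truth other
    n_ow: int = 0   # model other, truth woody
    n_oo: int = 0   # model other, truth other

    def __post_init__(self) -> None:
        if min(self.n_ww, self.n_wo, self.n_ow, self.n_oo) < 0:
            raise ParameterError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_ww + self.n_wo + self.n_ow + self.n_oo

    def as_array(self) -> np.ndarray:
        return np.array([[self.n_ww, self.n_wo], [self.n_ow, self.n_oo]])


def dominant_label(feature_classes: Sequence[str],
                   woody_classes: Iterable[str] | None = None) -> str:
    """Reduce the multiple features on one boundary to a single label.

    Woody features dominate: if any feature on the boundary is woody the
    boundary is woody, otherwise other.
    """
    if not feature_classes:
        raise ParameterError("feature class list is empty")
    woody = frozenset(woody_classes) if woody_classes is not None \
        else DEFAULT_WOODY_CLASSES
    return "woody" if any(c in woody for c in feature_classes) else "other"


def agreement_region(model_net: LinearNetwork, truth_net: LinearNetwork,
                     radius: float = 5.0):
    """Intersection of the two networks' buffers (round caps and joins)."""
    if radius <= 0:
        raise ParameterError(f"buffer radius must be > 0, got {radius}")
    bm = model_net.union().buffer(radius)
    bt = truth_net.union().buffer(radius)
    return bm.intersection(bt)


def sample_labeled_points(net: LinearNetwork, region, interval: float = 5.0,
                          source: str = "") -> list[LabeledPoint]:
    """Points at arc-length multiples of ``interval`` from each segment
    start, kept only inside ``region`` (boundary inclusive), carrying the
    segment's label (woody=1, other/unclassified=0)."""
    if interval <= 0:
        raise ParameterError(f"interval must be > 0, got {interval}")
    prepared = prep(region)
    out: list[LabeledPoint] = []
    for seg in net.segments:
        label = 1 if seg.label == "woody" else 0
        n = int(np.floor(seg.length / interval + 1e-9))
        for k in range(n + 1):
            p = seg.geometry.interpolate(min(k * interval, seg.length))
            if prepared.intersects(p):
                out.append(LabeledPoint(float(p.x), float(p.y), label, source))
    return out


def match_points(model_pts: Sequence[LabeledPoint],
                 truth_pts: Sequence[LabeledPoint],
                 max_dist: float = 10.0,
                 direction: str = "truth_to_model") -> ConfusionMatrix:
    """Nearest-neighbour pairing of the two point frameworks.

    By default each truth point is paired with its nearest model point
    within ``max_dist`` (ties broken by the smaller model-point index);
    unpaired points contribute nothing.  ``direction="model_to_truth"``
    reverses the roles (the matrix stays model x truth).
    """
    if max_dist <= 0:
        raise ParameterError(f"max_dist must be > 0, got {max_dist}")
    if direction not in {"truth_to_model", "model_to_truth"}:
        raise ParameterError(f"unknown direction {direction!r}")
    cm = ConfusionMatrix()
    if direction == "truth_to_model":
        queries, targets = truth_pts, model_pts
    else:
        queries, targets = model_pts, truth_pts
    if not queries or not targets:
        return cm
    coords = np.array([(p.x, p.y) for p in targets])
    tree = cKDTree(coords)
    for q in queries:
        d, i = tree.query((q.x, q.y))
        if d > max_dist:
            continue
        # deterministic tie-break: smallest index among equidistant targets
        cand = tree.query_ball_point((q.x, q.y), d + 1e-12)
        dists = np.hypot(coords[cand, 0] - q.x, coords[cand, 1] - q.y)
        i = min(int(c) for c, dc in zip(cand, dists) if dc <= d + 1e-12)
        t = targets[i]
        model_label = t.label if direction == "truth_to_model" else q.label
        truth_label = q.label if direction == "truth_to_model" else t.label
        if model_label == 1 and truth_label == 1:
            cm.n_ww += 1
        elif model_label == 1:
            cm.n_wo += 1
        elif truth_label == 1:
            cm.n_ow += 1
        else:
            cm.n_oo += 1
    return cm


def percent_agreement(cm: ConfusionMatrix, row: str = "woody") -> float:
    """Row-wise percent agreement (unrounded; round half-up for display)."""
    if row == "woody":
        diag, row_total = cm.n_ww, cm.n_ww + cm.n_wo
    elif row == "other":
        diag, row_total = cm.n_oo, cm.n_ow + cm.n_oo
    else:
        raise ParameterError(f"row must be 'woody' or 'other', got {row!r}")
    if row_total == 0:
        raise UndefinedStatisticError(f"{row} row of the confusion matrix is empty")
    return 100.0 * diag / row_total


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise UndefinedStatisticError("confusion matrix is empty")
    p_o = (cm.n_ww + cm.n_oo) / n
    row_w, row_o = cm.n_ww + cm.n_wo, cm.n_ow + cm.n_oo
    col_w, col_o = cm.n_ww + cm.n_ow, cm.n_wo + cm.n_oo
    p_e = (row_w * col_w + row_o * col_o) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def kappa_band(kappa: float) -> str:
    """Conventional Landis–Koch verbal band (report annotation only)."""
    if kappa < 0:
        return "poor"
    bands = [(0.20, "slight"), (0.40, "fair"), (0.60, "moderate"),
             (0.80, "substantial"), (1.01, "almost perfect")]
    for upper, name in bands:
        if kappa <= upper if upper == 1.01 else kappa < upper:
            return name
    return "almost perfect"


def density_map(net: LinearNetwork, origin_x: float, origin_y: float,
                n_x: int, n_y: int, cell_size: float = 1000.0) -> HeightGrid:
    """Woody boundary length per unit area on a coarse grid (m/km^2).

    Each cell's value is the clipped woody length inside the cell divided
    by the cell area in km^2.  ``origin_y`` is the grid's TOP edge; row 0
    is the northernmost row (standard raster layout).
    """
    from shapely.geometry import box

    woody = [s.geometry for s in net.segments if s.label == "woody"]
    area_km2 = (cell_size / 1000.0) ** 2
    values = np.zeros((n_y, n_x))
    for r in range(n_y):
        for c in range(n_x):
            cell = box(origin_x + c * cell_size, origin_y - (r + 1) * cell_size,
                       origin_x + (c + 1) * cell_size, origin_y - r * cell_size)
            length = sum(g.intersection(cell).length for g in woody)
            values[r, c] = length / area_km2
    return HeightGrid(origin_x, origin_y, cell_size, values, nodata=-9999.0)


def stratum_mean_density(density: HeightGrid,
                         cell_strata: Mapping[tuple[int, int], str]
                         ) -> dict[str, float]:
    """Mean cell density per stratum, in km/km^2.

    ``cell_strata`` maps (row, col) of the density grid to a stratum id.
    """
    acc: dict[str, list[float]] = {}
    for (r, c), sid in cell_strata.items():
        acc.setdefault(sid, []).append(density.values[r, c] / 1000.0)
    return {sid: float(np.mean(v)) for sid, v in acc.items()}
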