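"""Height attribution and the three-threshold woody/other classification.

A boundary segment is labelled *woody* (a hedge or line of trees) when the
canopy-height statistics along it satisfy all three of:

* minimum height >= ``min_h_floor`` (default -0.13 m; a ditch running beside
  the woody feature can pull the surface slightly below ground level),
* mean height >= ``mean_h_floor`` (default 0.58 m; hedges are gappy, so the
  mean over the whole boundary is well below typical shrub height),
* maximum height <= ``max_h_ceiling`` (default 58 m, the tallest tree in
  Great Britain — anything higher is a data artefact, not vegetation).

All comparisons are inclusive, so a segment sitting exactly on the
thresholds classifies as woody.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, StateError
from .grids import HeightGrid
from .network import BoundarySegment, LinearNetwork

__all__ = ["ThresholdSet", "attribute_segment", "classify_segment",
           "classify_network", "sample_distances"]


@dataclass(frozen=True)
class ThresholdSet:
    """The three classification height parameters, in metres."""

    min_h_floor: float = -0.13
    mean_h_floor: float = 0.58
    max_h_ceiling: float = 58.0

    def __post_init__(self) -> None:
        if not (self.min_h_floor <= self.mean_h_floor <= self.max_h_ceiling):
            raise ParameterError(
                "thresholds must satisfy min_h_floor <= mean_h_floor <= "
                f"max_h_ceiling, got {self}"
            )

    def replace(self, **kw) -> "ThresholdSet":
        d = {"min_h_floor": self.min_h_floor, "mean_h_floor": self.mean_h_floor,
             "max_h_ceiling": self.max_h_ceiling}
        d.update(kw)
        return ThresholdSet(**d)


def sample_distances(length: float, step: float) -> np.ndarray:
    """Arc-length positions every ``step`` from 0, always including the end."""
    if step <= 0:
        raise ParameterError(f"sample_step must be > 0, got {step}")
    d = np.arange(0.0, length, step)
    if length - d[-1] > 1e-9:
        d = np.append(d, length)
    else:
        d[-1] = length
    return d


def attribute_segment(seg: BoundarySegment, chm: HeightGrid,
                      sample_step: float | None = None) -> BoundarySegment:
    """Sample canopy heights along a segment and set min/max/mean.

    Points are placed every ``sample_step`` metres from the segment start
    (default: one CHM cell size) and both endpoints are always sampled.
    nodata samples are excluded from the statistics; if every sample is
    nodata the segment is labelled ``unclassified`` with unset statistics.
    """
    step = chm.cell_size if sample_step is None else sample_step
    dists = sample_distances(seg.length, step)
    pts = [seg.geometry.interpolate(d) for d in dists]
    xs = np.array([p.x for p in pts])
    ys = np.array([p.y for p in pts])
    values = chm.sample(xs, ys)
    ok = values != chm.nodata
    if not np.any(ok):
        return seg.with_attrs(min_h=None, max_h=None, mean_h=None,
                              label="unclassified")
    data = values[ok]
    return seg.with_attrs(min_h=float(data.min()), max_h=float(data.max()),
                          mean_h=float(data.mean()))


def classify_segment(seg: BoundarySegment, thr: ThresholdSet | None = None
                     ) -> BoundarySegment:
    """Label an attributed segment woody or other by the threshold rule."""
    thr = thr or ThresholdSet()
    if seg.min_h is None or seg.max_h is None or seg.mean_h is None:
        raise StateError(f"segment {seg.id} has no height attributes; "
                         "attribute_segment must run first")
    woody = (seg.min_h >= thr.min_h_floor
             and seg.mean_h >= thr.mean_h_floor
             and seg.max_h <= thr.max_h_ceiling)
    return seg.with_attrs(label="woody" if woody else "other")


def classify_network(net: LinearNetwork, chm: HeightGrid,
                     thr: ThresholdSet | None = None,
                     sample_step: float | None = None) -> LinearNetwork:
    """Attribute and classify every segment (order-independent)."""
    thr = thr or ThresholdSet()
    out = []
    for seg in net.segments:
        attributed = attribute_segment(seg, chm, sample_step)
        if attributed.label == "unclassified" and attributed.mean_h is None:
            out.append(attributed)
        else:
            out.append(classify_segment(attributed, thr))
    return LinearNetwork(out, net.crs_note)
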