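"""Stratified expansion of per-square woody lengths and threshold calibration.

National totals follow the classical stratified expansion estimator used by
field surveys of 1-km sample squares: for each land-class stratum the mean
woody length over its sampled squares is multiplied by the number of 1-km
squares in the stratum's population, and stratum totals are summed.

Threshold calibration is a deterministic coordinate-descent over the three
classification thresholds in 0.01-m increments, minimising the absolute
deviation of the stratified national total from a target length.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .classify import ThresholdSet
from .errors import (CompletenessError, ParameterError, SquareLookupError)
from .network import BoundarySegment, LinearNetwork, assign_ids

__all__ = [
    "StratumTable", "CalibrationSpec", "make_square_grid", "assign_squares",
    "square_woody_length", "per_square_woody_lengths", "stratified_total",
    "per_stratum_table", "calibrate_thresholds", "grid_search_thresholds",
    "make_threshold_evaluator", "length_ratio_report", "round_half_up",
]


@dataclass
class StratumTable:
    """Land-class strata: population square counts and sampled square ids."""

    rows: list[tuple[str, int, list[str]]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ParameterError("stratum ids must be unique")
        for sid, pop, sampled in self.rows:
            if not sampled:
                raise ParameterError(f"stratum {sid} has no sampled squares")
            if pop < len(sampled):
                raise ParameterError(
                    f"stratum {sid}: population {pop} < {len(sampled)} sampled squares"
                )

    @property
    def stratum_ids(self) -> list[str]:
        return [r[0] for r in self.rows]

    def sampled_ids(self) -> list[str]:
        return [sq for _, _, sampled in self.rows for sq in sampled]

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["stratum_id", "population_squares", "sampled_square_ids"])
            for sid, pop, sampled in self.rows:
                w.writerow([sid, pop, ";".join(sampled)])

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "StratumTable":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append((
                    rec["stratum_id"],
                    int(rec["population_squares"]),
                    [s for s in rec["sampled_square_ids"].split(";") if s],
                ))
        return cls(rows)


@dataclass
class CalibrationSpec:
    """Target and search space for threshold calibration."""

    target_total: float                       # km
    step: float = 0.01                        # m
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "min_h_floor": (-5.0, 5.0),
        "mean_h_floor": (0.0, 10.0),
        "max_h_ceiling": (10.0, 100.0),
    })
    max_sweeps: int = 50

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ParameterError(f"step must be > 0, got {self.step}")
        if self.max_sweeps < 1:
            raise ParameterError("max_sweeps must be >= 1")
        for name, (lo, hi) in self.ranges.items():
            if lo >= hi:
                raise ParameterError(f"range for {name} must have low < high")


# ---------------------------------------------------------------------------
# square membership and per-square lengths

def square_id_for(x: float, y: float, origin_x: float = 0.0, origin_y: float = 0.0,
                  size: float = 1000.0) -> str:
    i = int(np.floor((x - origin_x) / size))
    j = int(np.floor((y - origin_y) / size))
    return f"{i}_{j}"


def make_square_grid(origin_x: float, origin_y: float, n_x: int, n_y: int,
                     size: float = 1000.0) -> dict[str, Polygon]:
    """1-km (by default) square polygons keyed ``"<col>_<row>"`` with the
    row index increasing northwards from (origin_x, origin_y) at bottom-left."""
    return {
        f"{i}_{j}": box(origin_x + i * size, origin_y + j * size,
                        origin_x + (i + 1) * size, origin_y + (j + 1) * size)
        for i in range(n_x) for j in range(n_y)
    }


def assign_squares(net: LinearNetwork, squares: Mapping[str, Polygon]
                   ) -> LinearNetwork:
    """Clip every segment to the squares it crosses and tag membership.

    A segment straddling a square border is cut at the border so total
    length is conserved across squares.
    """
    geoms, attrs = [], []
    for seg in net.segments:
        for sq_id in sorted(squares):
            piece = seg.geometry.intersection(squares[sq_id])
            if piece.is_empty or piece.length <= 0:
                continue
            lines = [piece] if piece.geom_type == "LineString" else [
                g for g in piece.geoms if g.geom_type == "LineString"]
            for line in lines:
                geoms.append(line)
                attrs.append(dict(label=seg.label, min_h=seg.min_h,
                                  max_h=seg.max_h, mean_h=seg.mean_h,
                                  square_id=sq_id))
    return LinearNetwork(assign_ids(geoms, attrs), net.crs_note)


def square_woody_length(net: LinearNetwork, square_id: str,
                        squares: Mapping[str, Polygon] | None = None) -> float:
    """Total length (m) of woody-labelled boundary inside one square.

    With ``squares`` given, woody segments are clipped to the square
    geometry; otherwise segments must already carry ``square_id`` tags.
    An unknown id raises :class:`SquareLookupError`.
    """
    if squares is not None:
        if square_id not in squares:
            raise SquareLookupError(f"unknown square id {square_id!r}")
        sq = squares[square_id]
        return float(sum(
            s.geometry.intersection(sq).length
            for s in net.segments if s.label == "woody"
        ))
    known = {s.square_id for s in net.segments if s.square_id is not None}
    if square_id not in known:
        raise SquareLookupError(f"unknown square id {square_id!r}")
    return float(sum(s.length for s in net.segments
                     if s.label == "woody" and s.square_id == square_id))


def per_square_woody_lengths(net: LinearNetwork,
                             squares: Mapping[str, Polygon]) -> dict[str, float]:
    """Woody length (m) for every square in the grid (0 where none)."""
    woody = [s.geometry for s in net.segments if s.label == "woody"]
    out: dict[str, float] = {}
    for sq_id, sq in squares.items():
        out[sq_id] = float(sum(g.intersection(sq).length for g in woody))
    return out


# ---------------------------------------------------------------------------
# stratified expansion

def stratified_total(square_lengths: Mapping[str, float], strata: StratumTable,
                     weighted: bool = True) -> float:
    """National total in km.

    Weighted (default): sum over strata of population_squares x mean sampled
    length.  Unweighted: plain sum of the sampled-square lengths (the survey's
    alternative summing rule), with no population expansion.
    """
    missing = [sq for sq in strata.sampled_ids() if sq not in square_lengths]
    if missing:
        raise CompletenessError(f"missing square lengths for ids: {sorted(missing)}")
    total_m = 0.0
    for sid, pop, sampled in strata.rows:
        lengths = [square_lengths[sq] for sq in sampled]
        if weighted:
            total_m += pop * float(np.mean(lengths))
        else:
            total_m += float(np.sum(lengths))
    return total_m / 1000.0


def per_stratum_table(square_lengths: Mapping[str, float], strata: StratumTable
                      ) -> pd.DataFrame:
    """Per-stratum summary: sample count, mean m/square, expanded total km."""
    recs = []
    for sid, pop, sampled in strata.rows:
        lengths = [square_lengths[sq] for sq in sampled]
        mean_m = float(np.mean(lengths))
        recs.append({
            "stratum_id": sid, "population_squares": pop,
            "n_sampled": len(sampled), "mean_length_m": mean_m,
            "total_km": pop * mean_m / 1000.0,
        })
    df = pd.DataFrame.from_records(recs)
    return df


# ---------------------------------------------------------------------------
# threshold calibration

_PARAM_ORDER = ("min_h_floor", "mean_h_floor", "max_h_ceiling")


def _in_ranges(thr: ThresholdSet, ranges) -> bool:
    for name in _PARAM_ORDER:
        lo, hi = ranges[name]
        if not (lo <= getattr(thr, name) <= hi):
            return False
    return True


def _try_replace(thr: ThresholdSet, name: str, value: float) -> ThresholdSet | None:
    try:
        return thr.replace(**{name: value})
    except ParameterError:
        return None


def calibrate_thresholds(
    evaluate: Callable[[ThresholdSet], float],
    spec: CalibrationSpec,
    start: ThresholdSet | None = None,
    log: list | None = None,
) -> tuple[ThresholdSet, float]:
    """Sequential coordinate search over the three thresholds in 0.01-m steps.

    ``evaluate`` maps a candidate :class:`ThresholdSet` to the stratified
    national total (km); the objective is ``|total - target_total|``.
    Parameters are varied sequentially in the fixed order (min_h_floor,
    mean_h_floor, max_h_ceiling): each in turn is scanned over its range at
    ``step`` increments with the other two held fixed, and moves to the
    value minimising the objective.  Because the objective is piecewise
    constant in each threshold, ties are broken deterministically: keep the
    incumbent on an exact tie, otherwise prefer the candidate closest to
    the incumbent, then the smaller value.  Sweeps repeat until a full
    sweep changes nothing or ``max_sweeps`` is reached.  Returns the best
    ThresholdSet and its objective (km); every candidate evaluated is
    appended to ``log`` as (ThresholdSet, total_km, objective).
    """
    start = start or ThresholdSet()
    if not _in_ranges(start, spec.ranges):
        raise ParameterError(f"start thresholds {start} outside calibration ranges")

    def objective(thr: ThresholdSet) -> float:
        total = evaluate(thr)
        obj = abs(total - spec.target_total)
        if log is not None:
            log.append((thr, total, obj))
        return obj

    best, best_obj = start, objective(start)
    for _ in range(spec.max_sweeps):
        changed = False
        for name in _PARAM_ORDER:
            lo, hi = spec.ranges[name]
            incumbent = getattr(best, name)
            n = int(round((hi - lo) / spec.step))
            # incumbent key sorts before any tying candidate (distance 0)
            best_key = (best_obj, 0.0, incumbent)
            chosen = None
            for k in range(n + 1):
                v = lo + k * spec.step
                if v == incumbent:
                    continue
                cand = _try_replace(best, name, v)
                if cand is None:
                    continue
                key = (objective(cand), abs(v - incumbent), v)
                if key < best_key:
                    best_key, chosen = key, cand
            if chosen is not None:
                best, best_obj = chosen, best_key[0]
                changed = True
        if not changed:
            break
    return best, best_obj


def make_threshold_evaluator(net: LinearNetwork,
                             squares: Mapping[str, Polygon],
                             strata: StratumTable,
                             weighted: bool = True
                             ) -> Callable[[ThresholdSet], float]:
    """Fast closure mapping a ThresholdSet to the stratified total (km).

    Per-segment clipped lengths per square depend only on geometry, so they
    are precomputed once; each candidate evaluation is then a vectorised
    re-application of the three inclusive comparisons.
    """
    segs = [s for s in net.segments if s.mean_h is not None]
    mins = np.array([s.min_h for s in segs])
    means = np.array([s.mean_h for s in segs])
    maxs = np.array([s.max_h for s in segs])
    sq_ids = sorted(squares)
    sq_pos = {sq: i for i, sq in enumerate(sq_ids)}
    clip = np.zeros((len(segs), len(sq_ids)))
    for i, s in enumerate(segs):
        for sq in sq_ids:
            piece = s.geometry.intersection(squares[sq])
            if not piece.is_empty:
                clip[i, sq_pos[sq]] = piece.length

    def evaluate(thr: ThresholdSet) -> float:
        woody = ((mins >= thr.min_h_floor) & (means >= thr.mean_h_floor)
                 & (maxs <= thr.max_h_ceiling))
        lengths = dict(zip(sq_ids, clip[woody].sum(axis=0)))
        return stratified_total(lengths, strata, weighted=weighted)

    return evaluate


def grid_search_thresholds(
    evaluate: Callable[[ThresholdSet], float],
    spec: CalibrationSpec,
) -> tuple[ThresholdSet, float]:
    """Exhaustive grid search (small ranges only); same objective as the
    coordinate descent.  Ties resolve to the first candidate in sweep order."""
    axes = []
    for name in _PARAM_ORDER:
        lo, hi = spec.ranges[name]
        n = int(round((hi - lo) / spec.step)) + 1
        axes.append(lo + spec.step * np.arange(n))
    best: ThresholdSet | None = None
    best_obj = float("inf")
    for a in axes[0]:
        for b in axes[1]:
            for c in axes[2]:
                try:
                    cand = ThresholdSet(float(a), float(b), float(c))
                except ParameterError:
                    continue
                obj = abs(evaluate(cand) - spec.target_total)
                if obj < best_obj:
                    best, best_obj = cand, obj
    if best is None:
        raise ParameterError("no valid threshold combination in the given ranges")
    return best, best_obj


# ---------------------------------------------------------------------------
# reporting

def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def length_ratio_report(totals: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    """Compare model totals against survey totals (both km).

    ``totals`` maps region name -> (model_km, survey_km).  Returns a table
    with the model/survey ratio as a half-up-rounded percentage and the
    shortfall (100 - ratio).
    """
    recs = []
    for region, (model_km, survey_km) in totals.items():
        if survey_km <= 0:
            raise ParameterError(f"survey total for {region} must be > 0")
        ratio = 100.0 * model_km / survey_km
        recs.append({
            "region": region, "model_km": model_km, "survey_km": survey_km,
            "ratio_pct": round_half_up(ratio),
            "shortfall_pct": round_half_up(100.0 - ratio),
        })
    return pd.DataFrame.from_records(recs)
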