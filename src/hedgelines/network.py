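"""Linear spatial framework: boundary segments dissolved from a field mosaic.

The boundary network is built by dissolving a polygon mosaic so that every
shared edge between adjacent fields appears exactly once, then noding the
linework (splitting at every intersection).  Each resulting segment is the
unit of attribution and classification.

By default segments are the primitive noded edges of the dissolved
arrangement (an isolated ring with no junctions stays one closed segment);
``merge_chains=True`` instead merges runs of degree-2 vertices so that
segment endpoints are exactly the junctions of the boundary graph.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import shapely
from shapely.geometry import LineString, MultiLineString, Polygon, mapping, shape
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .errors import GeometryError, ParameterError

Coord = tuple[float, float]

_LABELS = ("woody", "other", "unclassified")


@dataclass
class BoundarySegment:
    """One boundary line with its height attributes and class label."""

    id: str
    geometry: LineString
    label: str = "unclassified"
    min_h: float | None = None
    max_h: float | None = None
    mean_h: float | None = None
    square_id: str | None = None

    def __post_init__(self) -> None:
        if self.geometry.length <= 0:
            raise GeometryError(f"segment {self.id} has zero length")
        if self.label not in _LABELS:
            raise ParameterError(f"unknown label {self.label!r}")

    @property
    def coords(self) -> list[Coord]:
        return [(float(x), float(y)) for x, y in self.geometry.coords]

    @property
    def length(self) -> float:
        return self.geometry.length

    @property
    def is_attributed(self) -> bool:
        return self.mean_h is not None

    def with_attrs(self, **kwargs) -> "BoundarySegment":
        return replace(self, **kwargs)


@dataclass
class LinearNetwork:
    """A collection of noded boundary segments on a planar grid."""

    segments: list[BoundarySegment] = field(default_factory=list)
    crs_note: str = "planar metres (British-National-Grid-like)"

    def __iter__(self) -> Iterator[BoundarySegment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def total_length(self) -> float:
        return sum(s.length for s in self.segments)

    def woody_length(self) -> float:
        return sum(s.length for s in self.segments if s.label == "woody")

    def geometries(self) -> list[LineString]:
        return [s.geometry for s in self.segments]

    def union(self) -> shapely.Geometry:
        if not self.segments:
            return LineString()
        return unary_union(self.geometries())

    def copy(self) -> "LinearNetwork":
        return LinearNetwork([replace(s) for s in self.segments], self.crs_note)


def _segment_sort_key(geom: LineString):
    cs = list(geom.coords)
    a, b = cs[0], cs[-1]
    lo, hi = (a, b) if a <= b else (b, a)
    return (lo, hi, tuple(cs))


def assign_ids(geoms: Sequence[LineString], attrs: Sequence[dict] | None = None
               ) -> list[BoundarySegment]:
    """Build segments with reproducible ids: sort by (min-endpoint,
    max-endpoint) lexicographic order, then number."""
    if attrs is None:
        attrs = [{} for _ in geoms]
    order = sorted(range(len(geoms)), key=lambda i: _segment_sort_key(geoms[i]))
    return [
        BoundarySegment(id=f"s{n:06d}", geometry=geoms[i], **attrs[i])
        for n, i in enumerate(order)
    ]


def _explode(geom) -> list[LineString]:
    if geom.is_empty:
        return []
    if isinstance(geom, LineString):
        return [geom]
    return [g for g in geom.geoms if isinstance(g, LineString) and g.length > 0]


def _primitive_edges(lines: Iterable[LineString]) -> list[tuple[Coord, Coord]]:
    edges: list[tuple[Coord, Coord]] = []
    seen: set[tuple[Coord, Coord]] = set()
    for line in lines:
        cs = list(line.coords)
        for a, b in zip(cs[:-1], cs[1:]):
            a = (float(a[0]), float(a[1]))
            b = (float(b[0]), float(b[1]))
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            edges.append(key)    # canonical orientation: input-order invariant
    return edges


def _edge_graph(edges: Sequence[tuple[Coord, Coord]]):
    adjacency: dict[Coord, list[int]] = {}
    for i, (a, b) in enumerate(edges):
        adjacency.setdefault(a, []).append(i)
        adjacency.setdefault(b, []).append(i)
    return adjacency


def _components(edges, adjacency) -> list[list[int]]:
    seen_edges: set[int] = set()
    comps: list[list[int]] = []
    for start in range(len(edges)):
        if start in seen_edges:
            continue
        comp, stack = [], [start]
        seen_edges.add(start)
        while stack:
            e = stack.pop()
            comp.append(e)
            for v in edges[e]:
                for nb in adjacency[v]:
                    if nb not in seen_edges:
                        seen_edges.add(nb)
                        stack.append(nb)
        comps.append(comp)
    return comps


def _walk_ring(edge_ids: list[int], edges, adjacency) -> LineString:
    """Reconstruct a closed ring from a junction-free component."""
    in_comp = set(edge_ids)
    start_edge = min(edge_ids)
    a, b = edges[start_edge]
    path = [a, b]
    used = {start_edge}
    current = b
    while current != a:
        nxt = next(e for e in adjacency[current] if e in in_comp and e not in used)
        used.add(nxt)
        u, v = edges[nxt]
        current = v if u == current else u
        path.append(current)
    return LineString(path)


def _walk_chains(edge_ids: list[int], edges, adjacency) -> list[LineString]:
    """Merge degree-2 runs: one polyline per junction-to-junction chain."""
    in_comp = set(edge_ids)
    degree = {
        v: sum(1 for e in adjacency[v] if e in in_comp)
        for e in edge_ids
        for v in edges[e]
    }
    junctions = {v for v, d in degree.items() if d != 2}
    used: set[int] = set()
    chains: list[LineString] = []
    for j in sorted(junctions):
        for e0 in sorted(adjacency[j]):
            if e0 not in in_comp or e0 in used:
                continue
            path = [j]
            current, e = j, e0
            while True:
                used.add(e)
                u, v = edges[e]
                current = v if u == current else u
                path.append(current)
                if current in junctions:
                    break
                e = next(k for k in adjacency[current] if k in in_comp and k != e)
            chains.append(LineString(path))
    # junction-free loops hanging off nothing cannot occur inside a component
    # that has at least one junction, but a lollipop loop re-entering its own
    # junction is handled by the loop above (it starts and ends at j).
    return chains


def polygons_to_network(polygons: Sequence[Polygon], merge_chains: bool = False
                        ) -> LinearNetwork:
    """Dissolve a polygon mosaic into a noded boundary-line network.

    Every edge shared by two adjacent polygons appears exactly once.  Output
    segments are primitive noded edges (or junction-to-junction chains with
    ``merge_chains=True``); a ring with no junctions stays one closed segment.
    """
    rings: list[LineString] = []
    for i, poly in enumerate(polygons):
        if not isinstance(poly, Polygon) or poly.is_empty:
            raise GeometryError(f"input {i} is not a polygon")
        if not poly.is_valid:
            raise GeometryError(f"invalid polygon at index {i}")
        rings.append(LineString(poly.exterior.coords))
        rings.extend(LineString(r.coords) for r in poly.interiors)
    if not rings:
        return LinearNetwork([])

    dissolved = unary_union(rings)
    edges = _primitive_edges(_explode(dissolved))
    adjacency = _edge_graph(edges)
    degree = {v: len(ids) for v, ids in adjacency.items()}

    geoms: list[LineString] = []
    for comp in _components(edges, adjacency):
        comp_vertices = {v for e in comp for v in edges[e]}
        if all(degree[v] == 2 for v in comp_vertices):
            geoms.append(_walk_ring(comp, edges, adjacency))
        elif merge_chains:
            geoms.extend(_walk_chains(comp, edges, adjacency))
        else:
            geoms.extend(LineString(edges[e]) for e in comp)
    return LinearNetwork(assign_ids(geoms))


def generalize(net: LinearNetwork, tolerance: float = 0.0) -> LinearNetwork:
    """Douglas–Peucker simplification of every segment; endpoints preserved.

    ``tolerance`` is the maximum allowed perpendicular offset (m); 0 leaves
    the network unchanged.
    """
    if tolerance < 0:
        raise ParameterError(f"tolerance must be >= 0, got {tolerance}")
    if tolerance == 0:
        return net.copy()
    segments = [
        replace(s, geometry=s.geometry.simplify(tolerance, preserve_topology=False))
        for s in net.segments
    ]
    return LinearNetwork(segments, net.crs_note)


def split_segments(net: LinearNetwork) -> LinearNetwork:
    """Cut segments at every interior crossing or touch; the result is noded.

    Attributes (label, heights, square membership) are inherited from the
    parent segment of each piece; ids are re-assigned deterministically.
    """
    if not net.segments:
        return net.copy()
    geoms = net.geometries()
    noded = shapely.node(MultiLineString(geoms))
    pieces = _explode(noded)
    tree = STRtree(geoms)
    out_geoms: list[LineString] = []
    out_attrs: list[dict] = []
    for piece in pieces:
        mid = piece.interpolate(0.5, normalized=True)
        cand = tree.query(mid.buffer(1e-6))
        if len(cand) == 0:
            cand = range(len(geoms))
        parent_idx = min(cand, key=lambda i: (geoms[i].distance(mid), i))
        parent = net.segments[int(parent_idx)]
        out_geoms.append(piece)
        out_attrs.append(dict(label=parent.label, min_h=parent.min_h,
                              max_h=parent.max_h, mean_h=parent.mean_h,
                              square_id=parent.square_id))
    return LinearNetwork(assign_ids(out_geoms, out_attrs), net.crs_note)


# ---------------------------------------------------------------------------
# GeoJSON plumbing

def write_network(net: LinearNetwork, path: str | os.PathLike) -> None:
    features = []
    for s in net.segments:
        features.append({
            "type": "Feature",
            "geometry": mapping(s.geometry),
            "properties": {
                "id": s.id, "label": s.label, "min_h": s.min_h,
                "max_h": s.max_h, "mean_h": s.mean_h, "square_id": s.square_id,
            },
        })
    doc = {"type": "FeatureCollection", "crs_note": net.crs_note,
           "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_network(path: str | os.PathLike, woody_classes: set[str] | None = None
                 ) -> LinearNetwork:
    """Read a line network from GeoJSON.

    Features carry either a ready ``label`` property or a ``classes``
    property (list or ';'-joined string of per-feature class names, e.g.
    from a field survey); in the latter case the label is reduced with
    woody-dominance via :func:`hedgelines.validate.dominant_label`.
    """
    from .validate import dominant_label

    with open(path) as fh:
        doc = json.load(fh)
    segments: list[BoundarySegment] = []
    for n, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        lines = _explode(geom) if geom.geom_type == "MultiLineString" else [geom]
        label = props.get("label")
        if label is None and "classes" in props:
            classes = props["classes"]
            if isinstance(classes, str):
                classes = [c for c in classes.split(";") if c]
            label = dominant_label(classes, woody_classes=woody_classes)
        for k, line in enumerate(lines):
            seg_id = props.get("id") or f"f{n:06d}"
            if len(lines) > 1:
                seg_id = f"{seg_id}.{k}"
            segments.append(BoundarySegment(
                id=seg_id, geometry=line,
                label=label or "unclassified",
                min_h=props.get("min_h"), max_h=props.get("max_h"),
                mean_h=props.get("mean_h"), square_id=props.get("square_id"),
            ))
    return LinearNetwork(segments, doc.get("crs_note", "planar metres"))


def write_polygons(polygons: Sequence[Polygon], path: str | os.PathLike) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(p), "properties": {"id": i}}
            for i, p in enumerate(polygons)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_polygons(path: str | os.PathLike) -> list[Polygon]:
    with open(path) as fh:
        doc = json.load(fh)
    polys: list[Polygon] = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "Polygon":
            polys.append(geom)
        elif geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
        else:
            raise GeometryError(f"expected polygons, found {geom.geom_type}")
    return polys


def is_noded(net: LinearNetwork, tol: float = 1e-9) -> bool:
    """Brute-force all-pairs check that segments meet only at endpoints."""
    segs = net.segments
    for i in range(len(segs)):
        gi = segs[i].geometry
        ends_i = {tuple(map(float, gi.coords[0])), tuple(map(float, gi.coords[-1]))}
        for j in range(i + 1, len(segs)):
            gj = segs[j].geometry
            inter = gi.intersection(gj)
            if inter.is_empty:
                continue
            if inter.geom_type not in {"Point", "MultiPoint"}:
                return False
            pts = [inter] if inter.geom_type == "Point" else list(inter.geoms)
            ends_j = {tuple(map(float, gj.coords[0])),
                      tuple(map(float, gj.coords[-1]))}
            for p in pts:
                pt = (p.x, p.y)
                if not (
                    any(math.dist(pt, e) <= tol for e in ends_i)
                    and any(math.dist(pt, e) <= tol for e in ends_j)
                ):
                    return False
    return True
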