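"""Multi-scale landscape composition and configuration metrics.

Landscape structure is quantified in two kinds of zones: circular buffers
around each population centre (node level; radii 125, 250, 500, 1000 and
2000 m) and rectangular strips connecting population-centre pairs (link
level; width-to-length ratios 1:7, 1:5, 1:3, 1:2 and 2:3).  Within each
zone the module computes percent cover of area-based land-use classes
(with decade-frequency crop weighting for arable parcels), relative length
of linear elements (m/ha), Shannon diversity of land-use, parcel edge
density, the proportion of green settlement area, and the orientation
decomposition of linear elements into components parallel and orthogonal
to the gene-dispersal reference direction.

All coordinates must be planar projected meters (no geographic CRS
support).  Buffer discs are approximated by 256-vertex polygons; zones are
clipped to the window extent and denominators always use the clipped area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import (
    LineString,
    MultiLineString,
    MultiPolygon,
    Point,
    Polygon,
    box,
)
from shapely.geometry.base import BaseGeometry

log = logging.getLogger("landgen.landscape")

AREA_CLASSES = (
    "FOREST",
    "GRASS",
    "SEMNATGRASS",
    "SEMNATVEG",
    "ARABLE",
    "ORCHARD",
    "SETTLE",
    "OTHER",
)
CROP_TYPES = ("RAPE", "MAIZE", "CEREAL")
LINE_CLASSES = ("LWOOD", "LWATER", "LFRINGE", "LROAD")
BUFFER_DISTANCES = (125.0, 250.0, 500.0, 1000.0, 2000.0)
STRIP_RATIOS = ("1:7", "1:5", "1:3", "1:2", "2:3")
CROP_YEARS = tuple(range(2008, 2018))

OP_STABILIZER_M = 1.0  # additive stabilizer (meters) in the O:P ratio
BUFFER_QUAD_SEGS = 64  # 256-vertex disc approximation

M2_PER_HA = 10_000.0


def ratio_value(ratio: str) -> float:
    """'1:5' -> 0.2 (width / length)."""
    num, den = ratio.split(":")
    return float(num) / float(den)


# ---------------------------------------------------------------------------
# containers

@dataclass
class LandusePolygon:
    geometry: Polygon
    landuse: str
    green_fraction: float | None = None  # SETTLE only
    crop_years: dict | None = None  # ARABLE only: {year: crop}


@dataclass
class LinearElement:
    geometry: LineString
    line_class: str


@dataclass
class LandscapeWindow:
    """A square study window: land-use mosaic plus linear elements."""

    window_id: object
    extent: Polygon
    polygons: list
    lines: list

    def __post_init__(self) -> None:
        for p in self.polygons:
            if p.landuse not in AREA_CLASSES:
                raise ValueError(f"unknown land-use class {p.landuse!r}")
        for l in self.lines:
            if l.line_class not in LINE_CLASSES:
                raise ValueError(f"unknown line class {l.line_class!r}")

    def validate_overlap(self, tol: float = 1e-6) -> None:
        """Check pairwise parcel overlap is below tolerance (m^2)."""
        geoms = [p.geometry for p in self.polygons]
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                if geoms[i].intersects(geoms[j]):
                    inter = geoms[i].intersection(geoms[j])
                    if inter.area > tol:
                        raise ValueError(
                            f"parcels {i} and {j} overlap by {inter.area:.3g} m^2"
                        )


@dataclass
class Zone:
    """A buffer or strip clipped to the window extent."""

    geometry: Polygon
    kind: str  # "buffer" | "strip"
    scale: object  # buffer distance (m) or ratio string
    focus: object  # centre point (buffer) or (c1, c2) pair (strip)
    area_ha: float

    def __post_init__(self) -> None:
        if self.kind not in ("buffer", "strip"):
            raise ValueError(f"kind must be buffer or strip, got {self.kind!r}")
        if self.area_ha <= 0:
            raise ValueError("zone area must be positive")


# ---------------------------------------------------------------------------
# zones

def make_buffer(centre: Point, distance_m: float, window: LandscapeWindow) -> Zone:
    """Disc of the given radius around a population centre, clipped to the
    window extent."""
    if distance_m <= 0:
        raise ValueError("buffer distance must be positive")
    centre = Point(centre)
    if not window.extent.covers(centre):
        raise ValueError("centre lies outside the window extent")
    disc = centre.buffer(distance_m, quad_segs=BUFFER_QUAD_SEGS)
    clipped = disc.intersection(window.extent)
    return Zone(clipped, "buffer", distance_m, centre, clipped.area / M2_PER_HA)


def make_strip(c1: Point, c2: Point, ratio: str, window: LandscapeWindow) -> Zone:
    """Rectangle with long axis from c1 to c2 and width = ratio * length,
    clipped to the window extent."""
    c1, c2 = Point(c1), Point(c2)
    length = c1.distance(c2)
    if length == 0:
        raise ValueError("strip endpoints coincide")
    w = ratio_value(ratio) * length
    ux, uy = (c2.x - c1.x) / length, (c2.y - c1.y) / length
    nx, ny = -uy, ux  # unit normal
    h = w / 2.0
    corners = [
        (c1.x + nx * h, c1.y + ny * h),
        (c2.x + nx * h, c2.y + ny * h),
        (c2.x - nx * h, c2.y - ny * h),
        (c1.x - nx * h, c1.y - ny * h),
    ]
    rect = Polygon(corners)
    clipped = rect.intersection(window.extent)
    return Zone(clipped, "strip", ratio, (c1, c2), clipped.area / M2_PER_HA)


# ---------------------------------------------------------------------------
# area metrics

def crop_weight(parcel: LandusePolygon, crop: str) -> float:
    """Fraction of recorded years (2008-2017) the arable parcel grew `crop`."""
    if parcel.landuse != "ARABLE":
        raise ValueError("crop weights apply to ARABLE parcels only")
    years = parcel.crop_years or {}
    if not years:
        return 0.0
    hits = sum(1 for c in years.values() if c == crop)
    return hits / len(years)


def percent_cover(zone: Zone, window: LandscapeWindow, cls: str) -> float:
    """Percent of the zone covered by a land-use class or crop type.

    Crop types weight each arable parcel's clipped area by the fraction of
    years 2008-2017 the parcel grew that crop.
    """
    if zone.geometry.area == 0:
        raise ValueError("zone has zero area")
    total = 0.0
    if cls in CROP_TYPES:
        for p in window.polygons:
            if p.landuse != "ARABLE":
                continue
            a = p.geometry.intersection(zone.geometry).area
            if a > 0:
                total += a * crop_weight(p, cls)
    else:
        for p in window.polygons:
            if p.landuse != cls:
                continue
            total += p.geometry.intersection(zone.geometry).area
    return 100.0 * total / zone.geometry.area


def shannon_diversity(zone: Zone, window: LandscapeWindow) -> float:
    """Shannon index (natural log) over area proportions of the 8 area-based
    land-use classes present in the zone (crop split not used)."""
    areas = {}
    for p in window.polygons:
        a = p.geometry.intersection(zone.geometry).area
        if a > 0:
            areas[p.landuse] = areas.get(p.landuse, 0.0) + a
    total = sum(areas.values())
    if total == 0:
        return 0.0
    h = 0.0
    for a in areas.values():
        prop = a / total
        h -= prop * math.log(prop)
    return h


def edge_density(zone: Zone, window: LandscapeWindow) -> float:
    """Length of between-class parcel boundaries inside the zone per hectare.

    Only internal shared edges between parcels of different land-use class
    count; the zone outline and window border are excluded, so a uniform
    landscape scores 0.
    """
    if zone.area_ha <= 0:
        raise ValueError("zone has zero area")
    length = 0.0
    polys = window.polygons
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].landuse == polys[j].landuse:
                continue
            shared = polys[i].geometry.intersection(polys[j].geometry)
            if shared.is_empty:
                continue
            shared = shared.intersection(zone.geometry)
            length += _total_length(shared)
    return length / zone.area_ha


def green_settlement_fraction(zone: Zone, window: LandscapeWindow) -> float:
    """Area-weighted mean green fraction of settlement parcels in the zone;
    0 when no settlement is present."""
    num = den = 0.0
    for p in window.polygons:
        if p.landuse != "SETTLE":
            continue
        a = p.geometry.intersection(zone.geometry).area
        if a > 0:
            num += a * (p.green_fraction or 0.0)
            den += a
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# linear-element metrics

def _total_length(geom: BaseGeometry) -> float:
    """Summed length of the 1-D parts of a geometry (drops points/polygons)."""
    if geom.is_empty:
        return 0.0
    if isinstance(geom, LineString):
        return geom.length
    if isinstance(geom, MultiLineString):
        return sum(g.length for g in geom.geoms)
    if hasattr(geom, "geoms"):
        return sum(_total_length(g) for g in geom.geoms)
    return 0.0


def _clipped_pieces(line: LineString, zone_geom: Polygon) -> list[LineString]:
    """Connected pieces of a polyline clipped to a zone; each piece is one
    feature for the buffer-mode reference-direction rule."""
    clipped = line.intersection(zone_geom)
    pieces: list[LineString] = []

    def collect(g: BaseGeometry) -> None:
        if g.is_empty:
            return
        if isinstance(g, LineString):
            if g.length > 0:
                pieces.append(g)
        elif hasattr(g, "geoms"):
            for sub in g.geoms:
                collect(sub)

    collect(clipped)
    return pieces


def relative_length(zone: Zone, window: LandscapeWindow, line_class: str) -> float:
    """Total clipped polyline length (m) of a class divided by zone area (ha)."""
    if zone.area_ha <= 0:
        raise ValueError("zone has zero area")
    total = 0.0
    for l in window.lines:
        if l.line_class != line_class:
            continue
        total += _total_length(l.geometry.intersection(zone.geometry))
    return total / zone.area_ha


def _segment_components(piece: LineString, u: np.ndarray) -> tuple[float, float]:
    """Per-segment |cos|/|sin| projections of a polyline onto unit vector u."""
    coords = np.asarray(piece.coords)
    deltas = np.diff(coords[:, :2], axis=0)
    lengths = np.hypot(deltas[:, 0], deltas[:, 1])
    keep = lengths > 0
    deltas, lengths = deltas[keep], lengths[keep]
    if len(lengths) == 0:
        return 0.0, 0.0
    dots = deltas @ u
    par = np.abs(dots)
    orth = np.sqrt(np.maximum(lengths**2 - dots**2, 0.0))
    return float(par.sum()), float(orth.sum())


def orientation_components(
    zone: Zone, window: LandscapeWindow, line_class: str
) -> tuple[float, float]:
    """Parallel and orthogonal length components (m) of a line class.

    The reference direction is the strip axis (strip zones) or, per clipped
    feature, the direction from the feature's arc-length midpoint to the
    population centre (buffer zones).  Each straight segment of length l at
    angle theta to the reference contributes l|cos theta| to the parallel
    and l|sin theta| to the orthogonal total.  A buffer feature whose
    midpoint coincides with the centre is counted fully orthogonal and
    logged.
    """
    if zone.kind == "strip":
        c1, c2 = zone.focus
        axis = np.array([c2.x - c1.x, c2.y - c1.y])
        u_strip = axis / np.linalg.norm(axis)
    par_total = orth_total = 0.0
    for l in window.lines:
        if l.line_class != line_class:
            continue
        for piece in _clipped_pieces(l.geometry, zone.geometry):
            if zone.kind == "strip":
                u = u_strip
            else:
                centre = zone.focus
                mid = piece.interpolate(0.5, normalized=True)
                v = np.array([centre.x - mid.x, centre.y - mid.y])
                norm = np.linalg.norm(v)
                if norm == 0:
                    log.warning(
                        "feature midpoint coincides with population centre; "
                        "counted fully orthogonal"
                    )
                    orth_total += piece.length
                    continue
                u = v / norm
            p, o = _segment_components(piece, u)
            par_total += p
            orth_total += o
    return par_total, orth_total


def op_ratio(parallel_m: float, orthogonal_m: float, c: float = OP_STABILIZER_M) -> float:
    """Orthogonal-to-parallel ratio with a 1 m additive stabilizer."""
    if parallel_m < 0 or orthogonal_m < 0:
        raise ValueError("length components must be non-negative")
    return (orthogonal_m + c) / (parallel_m + c)


# ---------------------------------------------------------------------------
# metric tables

def _scale_label(scale: object) -> str:
    if isinstance(scale, float) and scale.is_integer():
        return str(int(scale))
    return str(scale)


def _zone_metrics(
    zone: Zone, window: LandscapeWindow, crop_split: bool = True
) -> dict[str, float]:
    """All per-zone metrics (unsuffixed names)."""
    out: dict[str, float] = {}
    for cls in AREA_CLASSES:
        out[cls] = percent_cover(zone, window, cls)
    if crop_split:
        for crop in CROP_TYPES:
            out[crop] = percent_cover(zone, window, crop)
    for lc in LINE_CLASSES:
        out[lc] = relative_length(zone, window, lc)
        par, orth = orientation_components(zone, window, lc)
        out[f"OP_{lc}"] = op_ratio(par, orth)
    out["SHANNON"] = shannon_diversity(zone, window)
    out["EDGEDEN"] = edge_density(zone, window)
    out["PROPGREEN"] = green_settlement_fraction(zone, window)
    return out


def compute_node_metrics(
    window: LandscapeWindow,
    nodes: Mapping[object, Point],
    scales: Sequence[float] = BUFFER_DISTANCES,
    crop_split: bool = True,
) -> pd.DataFrame:
    """Node-level metric table: one row per population, columns METRIC_scale."""
    rows = {}
    for pop, centre in nodes.items():
        row: dict[str, float] = {}
        for dist in scales:
            try:
                zone = make_buffer(centre, dist, window)
                metrics = _zone_metrics(zone, window, crop_split=crop_split)
            except Exception as exc:  # propagate as missing with a log entry
                log.warning("node %s scale %s failed: %s", pop, dist, exc)
                metrics = {}
            for name, val in metrics.items():
                row[f"{name}_{_scale_label(dist)}"] = val
        rows[pop] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "population"
    return df


def compute_link_metrics(
    window: LandscapeWindow,
    pairs: Mapping[tuple, tuple],
    ratios: Sequence[str] = STRIP_RATIOS,
    crop_split: bool = True,
) -> pd.DataFrame:
    """Link-level metric table: one row per population pair, columns
    METRIC_ratio.  `pairs` maps (pop1, pop2) -> (centre1, centre2)."""
    rows = {}
    for (a, b), (c1, c2) in pairs.items():
        row: dict[str, float] = {}
        for ratio in ratios:
            try:
                zone = make_strip(c1, c2, ratio, window)
                metrics = _zone_metrics(zone, window, crop_split=crop_split)
            except Exception as exc:
                log.warning("link %s-%s ratio %s failed: %s", a, b, ratio, exc)
                metrics = {}
            for name, val in metrics.items():
                row[f"{name}_{ratio}"] = val
        rows[(a, b)] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index, names=["pop1", "pop2"])
    return df


def metrics_metadata(
    scales: Sequence, decisions: Mapping | None = None
) -> dict:
    """Machine-readable provenance for a metric table."""
    meta = {
        "scales": [(_scale_label(s)) for s in scales],
        "op_stabilizer_m": OP_STABILIZER_M,
        "buffer_vertices": 4 * BUFFER_QUAD_SEGS,
        "crop_years": list(CROP_YEARS),
        "edge_density": "between-class internal boundaries only",
        "crop_weighting": "year-frequency",
    }
    if decisions:
        meta.update(decisions)
    return meta


# ---------------------------------------------------------------------------
# GeoJSON I/O (plain json; projected meters, no CRS handling by design)

def window_to_geojson(window: LandscapeWindow) -> dict:
    feats = []
    for p in window.polygons:
        props: dict = {"class": p.landuse}
        if p.green_fraction is not None:
            props["green_fraction"] = p.green_fraction
        if p.crop_years:
            props["crops"] = {str(y): c for y, c in p.crop_years.items()}
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": p.geometry.__geo_interface__,
            }
        )
    for l in window.lines:
        feats.append(
            {
                "type": "Feature",
                "properties": {"class": l.line_class},
                "geometry": l.geometry.__geo_interface__,
            }
        )
    return {
        "type": "FeatureCollection",
        "window_id": window.window_id,
        "extent": list(window.extent.bounds),
        "features": feats,
    }


def window_from_geojson(obj: dict) -> LandscapeWindow:
    from shapely.geometry import shape

    extent = box(*obj["extent"])
    polygons, lines = [], []
    for feat in obj["features"]:
        geom = shape(feat["geometry"])
        cls = feat["properties"]["class"]
        if isinstance(geom, (Polygon, MultiPolygon)):
            geoms = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
            crops = feat["properties"].get("crops")
            for g in geoms:
                polygons.append(
                    LandusePolygon(
                        g,
                        cls,
                        green_fraction=feat["properties"].get("green_fraction"),
                        crop_years={int(y): c for y, c in crops.items()} if crops else None,
                    )
                )
        else:
            geoms = geom.geoms if isinstance(geom, MultiLineString) else [geom]
            for g in geoms:
                lines.append(LinearElement(g, cls))
    return LandscapeWindow(obj.get("window_id", "W"), extent, polygons, lines)
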