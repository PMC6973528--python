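"""WGS84 geometry and spatial enrichment.

Points are longitude-first (CRS84 axis order) WKT, matching GeoSPARQL
``geo:wktLiteral`` conventions. Distance is great-circle (haversine) on
a sphere of mean radius 6371.0088 km. Containment is planar even-odd
ray casting in plate-carrée (lon, lat) coordinates, with boundary
points counted as inside; at Irish county scale the curvature error of
the planar rule is negligible — a documented limitation, not an
approximation the caller can change.

`materialize_spatial_links` is the enrichment step: it writes a direct
``avert:nearestStation`` / ``avert:withinRegion`` link per patient into
the graph so that later queries need no geospatial function, and records
the run as a provenance activity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

from .namespaces import AVERT, GEO, RDF, XSD
from .rdf_core import Graph, Iri, Triple, TypedLiteral

__all__ = [
    "GeoError",
    "AmbiguityError",
    "WktPoint",
    "RingPolygon",
    "Region",
    "parse_wkt_point",
    "format_wkt_point",
    "haversine_km",
    "point_in_polygon",
    "assign_region",
    "nearest_station",
    "materialize_spatial_links",
]

EARTH_RADIUS_KM = 6371.0088

#: The only CRS accepted in explicit wktLiteral CRS prefixes (CRS84 =
#: WGS84 with lon-first axis order, the GeoSPARQL default).
_ACCEPTED_CRS = {
    "http://www.opengis.net/def/crs/OGC/1.3/CRS84",
    "http://www.opengis.net/def/crs/EPSG/0/4326",
}


class GeoError(Exception):
    pass


class AmbiguityError(GeoError):
    """A point fell inside more than one region of a single level."""

    def __init__(self, region_ids: list[str]):
        super().__init__("point contained in multiple regions: " + ", ".join(region_ids))
        self.region_ids = region_ids


@dataclass(frozen=True)
class WktPoint:
    """A WGS84 point; ``lon`` degrees east, ``lat`` degrees north.

    Optional lexical forms preserve the input's printed precision so
    that format(parse(t)) == t.
    """

    lon: float
    lat: float
    lon_lex: str | None = field(default=None, compare=False)
    lat_lex: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (-180.0 <= self.lon <= 180.0):
            raise GeoError(f"longitude out of bounds: {self.lon}")
        if not (-90.0 <= self.lat <= 90.0):
            raise GeoError(f"latitude out of bounds: {self.lat}")


_POINT_RE = re.compile(
    r"^(?:<(?P<crs>[^>]+)>\s+)?POINT\s*\(\s*(?P<lon>[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)\s+"
    r"(?P<lat>[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)\s*\)$"
)


def parse_wkt_point(text: str) -> WktPoint:
    """Parse ``POINT (lon lat)``, optionally with a ``<CRS>`` prefix.

    The CRS prefix must be CRS84/WGS84 if present; any other explicit
    CRS is rejected rather than silently reinterpreted.
    """
    m = _POINT_RE.match(text.strip())
    if m is None:
        raise GeoError(f"not a WKT point: {text!r}")
    crs = m.group("crs")
    if crs is not None and crs not in _ACCEPTED_CRS:
        raise GeoError(f"unsupported CRS {crs!r}; only WGS84/CRS84 accepted")
    return WktPoint(
        lon=float(m.group("lon")),
        lat=float(m.group("lat")),
        lon_lex=m.group("lon"),
        lat_lex=m.group("lat"),
    )


def format_wkt_point(p: WktPoint) -> str:
    """Canonical ``POINT (lon lat)`` keeping full input precision."""
    lon = p.lon_lex if p.lon_lex is not None else repr(p.lon)
    lat = p.lat_lex if p.lat_lex is not None else repr(p.lat)
    return f"POINT ({lon} {lat})"


def _segments_intersect(a, b, c, d) -> bool:
    """Proper intersection test for the self-intersection check."""

    def orient(p, q, r):
        v = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
        return 0 if v == 0 else (1 if v > 0 else -1)

    o1, o2 = orient(a, b, c), orient(a, b, d)
    o3, o4 = orient(c, d, a), orient(c, d, b)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


@dataclass(frozen=True)
class RingPolygon:
    """Simple ring: ≥3 vertices, stored open (first ≠ last), closed
    implicitly, non-self-intersecting."""

    vertices: tuple[WktPoint, ...]

    def __post_init__(self):
        v = tuple(self.vertices)
        object.__setattr__(self, "vertices", v)
        if len(v) < 3:
            raise GeoError("polygon needs at least 3 vertices")
        if v[0] == v[-1]:
            raise GeoError("store polygons open: first vertex must differ from last")
        pts = [(p.lon, p.lat) for p in v]
        n = len(pts)
        # signed area ~ 0 → degenerate
        area2 = sum(
            pts[i][0] * pts[(i + 1) % n][1] - pts[(i + 1) % n][0] * pts[i][1] for i in range(n)
        )
        if abs(area2) < 1e-15:
            raise GeoError("degenerate polygon (zero area)")
        for i in range(n):
            for j in range(i + 1, n):
                if j == i or (j + 1) % n == i or (i + 1) % n == j:
                    continue  # shared-endpoint neighbours
                if _segments_intersect(pts[i], pts[(i + 1) % n], pts[j], pts[(j + 1) % n]):
                    raise GeoError(f"self-intersecting polygon (segments {i} and {j})")

    def to_wkt(self) -> str:
        ring = list(self.vertices) + [self.vertices[0]]
        coords = ", ".join(f"{format_coord(p.lon)} {format_coord(p.lat)}" for p in ring)
        return f"POLYGON (({coords}))"


def format_coord(x: float) -> str:
    s = repr(x)
    return s


_POLY_RE = re.compile(r"^POLYGON\s*\(\s*\((?P<ring>[^)]*)\)\s*\)$")


def parse_wkt_polygon(text: str) -> RingPolygon:
    m = _POLY_RE.match(text.strip())
    if m is None:
        raise GeoError(f"not a WKT polygon: {text!r}")
    pts = []
    for pair in m.group("ring").split(","):
        bits = pair.split()
        if len(bits) != 2:
            raise GeoError(f"bad coordinate pair: {pair!r}")
        pts.append(WktPoint(float(bits[0]), float(bits[1])))
    if len(pts) >= 2 and pts[0] == pts[-1]:
        pts = pts[:-1]  # accept closed rings, store open
    return RingPolygon(tuple(pts))


@dataclass(frozen=True)
class Region:
    id: Iri
    label: str
    polygon: RingPolygon
    level: str = "county"  # county | electoral_division | townland | lho


def haversine_km(a: WktPoint, b: WktPoint) -> float:
    """Great-circle distance in km on the mean-radius sphere.

    d = 2R·asin√(sin²(Δφ/2) + cosφ₁·cosφ₂·sin²(Δλ/2))
    """
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlmb = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _on_segment(px, py, ax, ay, bx, by) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > 1e-12:
        return False
    return min(ax, bx) - 1e-12 <= px <= max(ax, bx) + 1e-12 and min(ay, by) - 1e-12 <= py <= max(ay, by) + 1e-12


def point_in_polygon(p: WktPoint, poly: RingPolygon) -> bool:
    """Even-odd (ray casting) containment; boundary points are inside."""
    x, y = p.lon, p.lat
    pts = [(q.lon, q.lat) for q in poly.vertices]
    n = len(pts)
    inside = False
    for i in range(n):
        ax, ay = pts[i]
        bx, by = pts[(i + 1) % n]
        if _on_segment(x, y, ax, ay, bx, by):
            return True
        if (ay > y) != (by > y):
            # x-coordinate where the edge crosses the horizontal ray
            xcross = ax + (y - ay) * (bx - ax) / (by - ay)
            if x < xcross:
                inside = not inside
    return inside


def assign_region(p: WktPoint, regions: Sequence[Region]) -> Region | None:
    """The unique region containing ``p``; None if outside all.

    Regions are expected to be mutually non-overlapping (one level);
    containment in more than one raises :class:`AmbiguityError`.
    """
    hits = [r for r in regions if point_in_polygon(p, r.polygon)]
    if len(hits) > 1:
        raise AmbiguityError([r.id.value for r in hits])
    return hits[0] if hits else None


def nearest_station(p: WktPoint, stations: Sequence[tuple[Iri, WktPoint]]) -> tuple[Iri, float]:
    """Station minimizing great-circle distance; ties broken by
    lexicographically smallest IRI."""
    if not stations:
        raise GeoError("no stations supplied")
    best = min(((haversine_km(p, sp), iri) for iri, sp in stations), key=lambda t: (t[0], t[1].value))
    return best[1], best[0]


# ---------------------------------------------------------------------------
# graph-level enrichment


def _geometry_of(graph: Graph, subject: Iri) -> WktPoint | None:
    obj = graph.value(subject, GEO.asWKT)
    if obj is None or not isinstance(obj, TypedLiteral):
        return None
    try:
        return parse_wkt_point(obj.lexical)
    except GeoError:
        return None


def _double(x: float) -> TypedLiteral:
    return TypedLiteral(repr(x), XSD.double)


def materialize_spatial_links(
    graph: Graph,
    patients: Sequence[Iri] | None = None,
    stations: Sequence[Iri] | None = None,
    regions: Sequence[Region] | None = None,
    recorder=None,
) -> tuple[Graph, list[str]]:
    """Add nearest-station and region-containment links per patient.

    For each patient with a resolvable point geometry this adds
    ``avert:nearestStation`` (IRI), ``avert:nearestStationDistanceKm``
    (xsd:double) and, when a region contains the point,
    ``avert:withinRegion`` — 2 or 3 new triples per patient. Patients
    without geometry are skipped and reported. Idempotent under set
    semantics. If ``recorder`` (a :class:`geoweave.provenance.ProvRecorder`)
    is given, the run is recorded as a provenance activity covering the
    enriched subjects.

    Returns the graph and a list of warning strings.
    """
    if patients is None:
        patients = graph.subjects_of_type(AVERT.Patient)
    if stations is None:
        stations = graph.subjects_of_type(AVERT.WeatherStation)
    regions = list(regions or [])
    station_points = []
    for s in stations:
        sp = _geometry_of(graph, s)
        if sp is not None:
            station_points.append((s, sp))
    warnings: list[str] = []
    enriched: list[Iri] = []
    for patient in patients:
        p = _geometry_of(graph, patient)
        if p is None:
            warnings.append(f"patient {patient} has no point geometry; skipped")
            continue
        iri, dist = nearest_station(p, station_points)
        graph.add(Triple(patient, AVERT.nearestStation, iri))
        graph.add(Triple(patient, AVERT.nearestStationDistanceKm, _double(dist)))
        region = assign_region(p, regions)
        if region is not None:
            graph.add(Triple(patient, AVERT.withinRegion, region.id))
        enriched.append(patient)
    if recorder is not None:
        recorder.record_enrichment(
            graph,
            name="spatial-links",
            used=list(stations) + [r.id for r in regions],
            subjects=enriched,
            predicates=[AVERT.nearestStation, AVERT.nearestStationDistanceKm, AVERT.withinRegion],
        )
    return graph, warnings
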