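"""Geometry primitives and spatial enrichment against independent oracles."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from geoweave.geo import (
    EARTH_RADIUS_KM,
    AmbiguityError,
    GeoError,
    Region,
    RingPolygon,
    WktPoint,
    assign_region,
    format_wkt_point,
    haversine_km,
    materialize_spatial_links,
    nearest_station,
    parse_wkt_point,
    parse_wkt_polygon,
    point_in_polygon,
)
from geoweave.namespaces import AVERT, GEO, RDF
from geoweave.provenance import ProvRecorder, validate_provenance
from geoweave.rdf_core import Graph, Iri, Triple, TypedLiteral
from geoweave.namespaces import XSD


class TestWktPoint:
    def test_parse_lon_first(self):
        p = parse_wkt_point("POINT (-7.362222222 53.53722222)")
        assert p.lon == -7.362222222 and p.lat == 53.53722222

    @pytest.mark.parametrize(
        "text",
        ["POINT (-7.362222222 53.53722222)", "POINT (0 0)", "POINT (-10.5 51.25)"],
    )
    def test_format_parse_identity(self, text):
        assert format_wkt_point(parse_wkt_point(text)) == text

    def test_crs_prefix_accepted_for_wgs84(self):
        p = parse_wkt_point("<http://www.opengis.net/def/crs/OGC/1.3/CRS84> POINT (-7 53)")
        assert p.lon == -7.0

    def test_foreign_crs_rejected(self):
        with pytest.raises(GeoError, match="CRS"):
            parse_wkt_point("<http://www.opengis.net/def/crs/EPSG/0/2157> POINT (600000 750000)")

    @pytest.mark.parametrize("text", ["POINT (190 0)", "POINT (0 95)", "POINT (-181 10)"])
    def test_out_of_bounds_rejected(self, text):
        with pytest.raises(GeoError):
            parse_wkt_point(text)

    def test_not_a_point_rejected(self):
        with pytest.raises(GeoError):
            parse_wkt_point("LINESTRING (0 0, 1 1)")


_points = st.builds(
    WktPoint,
    st.floats(-179.0, 179.0),
    st.floats(-89.0, 89.0),
)


class TestHaversine:
    def test_zero_distance_to_self(self):
        p = WktPoint(-7.3, 53.5)
        assert haversine_km(p, p) == 0.0

    def test_quarter_great_circle(self):
        d = haversine_km(WktPoint(0, 0), WktPoint(90, 0))
        # closed form: quarter great circle = R·π/2 = 10007.5572... km
        assert d == pytest.approx(EARTH_RADIUS_KM * math.pi / 2, abs=1e-6)
        assert d == pytest.approx(10007.557, abs=1e-3)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(_points, _points)
    def test_symmetry_exact(self, a, b):
        assert haversine_km(a, b) == haversine_km(b, a)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(_points, _points, _points)
    def test_triangle_inequality(self, a, b, c):
        assert haversine_km(a, b) <= haversine_km(a, c) + haversine_km(c, b) + 1e-9


def _winding_number_contains(p: WktPoint, poly: RingPolygon) -> bool:
    """Independent containment oracle: nonzero winding number."""
    x, y = p.lon, p.lat
    pts = [(q.lon, q.lat) for q in poly.vertices]
    wn = 0
    n = len(pts)
    for i in range(n):
        ax, ay = pts[i]
        bx, by = pts[(i + 1) % n]
        if ay <= y:
            if by > y and (bx - ax) * (y - ay) - (by - ay) * (x - ax) > 0:
                wn += 1
        elif by <= y and (bx - ax) * (y - ay) - (by - ay) * (x - ax) < 0:
            wn -= 1
    return wn != 0


def _random_convex_polygon(rnd: random.Random) -> RingPolygon:
    cx, cy = rnd.uniform(-8, -6), rnd.uniform(52, 54)
    n = rnd.randint(3, 8)
    angles = sorted(rnd.uniform(0, 2 * math.pi) for _ in range(n))
    if len(set(angles)) < 3:
        angles = [i * 2 * math.pi / n for i in range(n)]
    r = rnd.uniform(0.2, 1.5)
    return RingPolygon(
        tuple(WktPoint(cx + r * math.cos(a), cy + r * math.sin(a)) for a in angles)
    )


UNIT_SQUARE = RingPolygon((WktPoint(0, 0), WktPoint(1, 0), WktPoint(1, 1), WktPoint(0, 1)))


class TestPointInPolygon:
    def test_centre_of_unit_square(self):
        assert point_in_polygon(WktPoint(0.5, 0.5), UNIT_SQUARE)

    def test_far_outside_bounding_box(self):
        assert not point_in_polygon(WktPoint(11, 0.5), UNIT_SQUARE)

    @pytest.mark.parametrize("p", [WktPoint(0, 0), WktPoint(0.5, 0), WktPoint(1, 1), WktPoint(0, 0.5)])
    def test_boundary_points_count_as_inside(self, p):
        assert point_in_polygon(p, UNIT_SQUARE)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(GeoError):
            RingPolygon((WktPoint(0, 0), WktPoint(1, 1), WktPoint(2, 2)))

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(GeoError, match="self-intersect"):
            RingPolygon(
                (WktPoint(0, 0), WktPoint(4, 0), WktPoint(4, 2), WktPoint(2, -1), WktPoint(0, 2))
            )

    def test_zero_area_bowtie_rejected(self):
        with pytest.raises(GeoError):
            RingPolygon((WktPoint(0, 0), WktPoint(1, 1), WktPoint(1, 0), WktPoint(0, 1)))

    def test_agrees_with_winding_number_oracle_on_random_pairs(self):
        rnd = random.Random(42)
        checked = 0
        for _ in range(1000):
            poly = _random_convex_polygon(rnd)
            p = WktPoint(rnd.uniform(-9, -5), rnd.uniform(51, 55))
            on_edge = any(
                abs(
                    (b.lon - a.lon) * (p.lat - a.lat) - (b.lat - a.lat) * (p.lon - a.lon)
                ) < 1e-9
                for a, b in zip(poly.vertices, poly.vertices[1:] + poly.vertices[:1])
            )
            if on_edge:
                continue  # boundary convention intentionally differs from the oracle
            assert point_in_polygon(p, poly) == _winding_number_contains(p, poly)
            checked += 1
        assert checked > 900

    def test_agrees_with_shapely(self):
        from shapely.geometry import Point, Polygon

        rnd = random.Random(7)
        for _ in range(300):
            poly = _random_convex_polygon(rnd)
            p = WktPoint(rnd.uniform(-9, -5), rnd.uniform(51, 55))
            sh = Polygon([(v.lon, v.lat) for v in poly.vertices])
            assert point_in_polygon(p, poly) == sh.covers(Point(p.lon, p.lat))

    def test_polygon_wkt_round_trip(self):
        assert parse_wkt_polygon(UNIT_SQUARE.to_wkt()) == UNIT_SQUARE


class TestAssignRegion:
    def _regions(self):
        return [
            Region(Iri(f"http://data.avert.ie/region/R{i}"), f"R{i}",
                   RingPolygon((WktPoint(i, 0), WktPoint(i + 1, 0), WktPoint(i + 1, 1), WktPoint(i, 1))))
            for i in range(3)
        ]

    def test_containing_region_found(self):
        r = assign_region(WktPoint(2.5, 0.5), self._regions())
        assert r.id.value.endswith("R2")

    def test_offshore_point_is_none(self):
        assert assign_region(WktPoint(10, 10), self._regions()) is None

    def test_overlapping_regions_raise_ambiguity(self):
        overlapping = [
            Region(Iri("http://x.org/A"), "A", UNIT_SQUARE),
            Region(Iri("http://x.org/B"), "B",
                   RingPolygon((WktPoint(-0.5, -0.5), WktPoint(1.5, -0.5), WktPoint(1.5, 1.5), WktPoint(-0.5, 1.5)))),
        ]
        with pytest.raises(AmbiguityError) as exc:
            assign_region(WktPoint(0.5, 0.5), overlapping)
        assert set(exc.value.region_ids) == {"http://x.org/A", "http://x.org/B"}


class TestNearestStation:
    def test_single_station(self):
        s = (Iri("http://x.org/s1"), WktPoint(-7, 53))
        iri, d = nearest_station(WktPoint(-7.5, 53.2), [s])
        assert iri == s[0] and d > 0

    def test_exact_tie_broken_by_smaller_iri(self):
        p = WktPoint(0, 10)
        stations = [
            (Iri("http://x.org/b"), WktPoint(1, 10)),
            (Iri("http://x.org/a"), WktPoint(-1, 10)),
        ]
        iri, _ = nearest_station(p, stations)
        assert iri.value == "http://x.org/a"

    def test_empty_station_list_rejected(self):
        with pytest.raises(GeoError):
            nearest_station(WktPoint(0, 0), [])

    def test_matches_brute_force_on_random_fixture(self):
        rnd = random.Random(11)
        stations = [
            (Iri(f"http://x.org/s{i:03d}"), WktPoint(rnd.uniform(-11, -5), rnd.uniform(51, 55.5)))
            for i in range(200)
        ]
        for _ in range(50):
            p = WktPoint(rnd.uniform(-11, -5), rnd.uniform(51, 55.5))
            got_iri, got_d = nearest_station(p, stations)
            brute = min(stations, key=lambda s: (haversine_km(p, s[1]), s[0].value))
            assert got_iri == brute[0]
            assert got_d == haversine_km(p, brute[1])


def _station_graph():
    g = Graph()
    for i, (lon, lat) in enumerate([(-7, 53), (-9, 52)]):
        s = Iri(f"http://x.org/station/{i}")
        g.add(Triple(s, RDF.type, AVERT.WeatherStation))
        g.add(Triple(s, GEO.asWKT, TypedLiteral(f"POINT ({lon} {lat})", GEO.wktLiteral)))
    return g


class TestMaterializeSpatialLinks:
    def _patients(self, g, n, with_geometry=True):
        out = []
        for i in range(n):
            p = Iri(f"http://x.org/patient/{i}")
            g.add(Triple(p, RDF.type, AVERT.Patient))
            if with_geometry:
                g.add(Triple(p, GEO.asWKT, TypedLiteral(f"POINT (-{7 + i * 0.01} 53.{i})", GEO.wktLiteral)))
            out.append(p)
        return out

    def _regions(self):
        return [
            Region(Iri("http://data.avert.ie/region/all"), "all",
                   RingPolygon((WktPoint(-11, 51), WktPoint(-5, 51), WktPoint(-5, 55.5), WktPoint(-11, 55.5))))
        ]

    def test_three_triples_per_contained_patient(self):
        g = _station_graph()
        self._patients(g, 10)
        before = len(g)
        materialize_spatial_links(g, regions=self._regions())
        assert len(g) - before == 30

    def test_patient_without_geometry_skipped_with_warning(self):
        g = _station_graph()
        p = Iri("http://x.org/patient/nogeo")
        g.add(Triple(p, RDF.type, AVERT.Patient))
        before = len(g)
        _, warnings = materialize_spatial_links(g, regions=self._regions())
        assert len(g) == before
        assert any("nogeo" in w for w in warnings)

    def test_rerun_is_idempotent_and_preserves_existing_triples(self):
        g = _station_graph()
        self._patients(g, 5)
        materialize_spatial_links(g, regions=self._regions())
        snapshot = set(g)
        materialize_spatial_links(g, regions=self._regions())
        assert set(g) == snapshot

    def test_recorder_makes_enrichment_provenance_complete(self):
        g = _station_graph()
        self._patients(g, 5)
        materialize_spatial_links(g, regions=self._regions(), recorder=ProvRecorder(agent="t"))
        assert validate_provenance(g) == []
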