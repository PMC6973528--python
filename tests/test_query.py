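"""Conjunctive query evaluation, week calendars, exposure windows."""

import itertools
import random
from datetime import date, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from geoweave.namespaces import AVERT, RDF, XSD
from geoweave.query import (
    DateRange,
    ExcludeHasTriple,
    IsoWeek,
    QueryError,
    QuerySpec,
    WeekEquals,
    build_query_spec,
    evaluate,
    exposure_window,
    iso_week_of,
    link_weekly_counts,
    parse_pattern,
)
from geoweave.rdf_core import Graph, Iri, Triple, TriplePattern, TypedLiteral, Var, match


class TestIsoWeek:
    @pytest.mark.parametrize(
        "day,expected",
        [
            ("2016-01-04", "2016-W01"),  # first Monday of ISO 2016
            ("2016-01-03", "2015-W53"),  # Sunday still in the old ISO year
            ("2015-12-31", "2015-W53"),
            ("2019-12-30", "2020-W01"),  # Monday already in the new ISO year
        ],
    )
    def test_iso_calendar(self, day, expected):
        assert str(iso_week_of(day)) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.dates(date(2000, 1, 1), date(2030, 1, 1)))
    def test_week_stable_monday_through_sunday(self, d):
        monday = d - timedelta(days=d.weekday())
        assert iso_week_of(monday.isoformat()) == iso_week_of((monday + timedelta(days=6)).isoformat())

    def test_cdc_weeks_start_sunday(self):
        # 2016-01-03 is a Sunday: first day of a CDC week, last of an ISO week
        assert iso_week_of("2016-01-03", "cdc") != iso_week_of("2016-01-02", "cdc")
        assert iso_week_of("2016-01-03") == iso_week_of("2016-01-02")

    def test_invalid_inputs(self):
        with pytest.raises(QueryError):
            iso_week_of("2016-13-01")
        with pytest.raises(QueryError):
            IsoWeek(2021, 53)  # 2021 has no ISO week 53
        assert IsoWeek.parse("2015-W53") == IsoWeek(2015, 53)


class TestExposureWindow:
    @pytest.mark.parametrize(
        "diag,n,start,end",
        [
            ("2015-03-10", 7, "2015-03-03", "2015-03-09"),
            ("2015-03-01", 1, "2015-02-28", "2015-02-28"),
            ("2016-03-01", 1, "2016-02-29", "2016-02-29"),  # leap day
        ],
    )
    def test_strictly_prior_window(self, diag, n, start, end):
        assert exposure_window(diag, n) == (date.fromisoformat(start), date.fromisoformat(end))

    def test_include_diagnosis_day_shifts_window(self):
        assert exposure_window("2015-03-10", 7, include_diagnosis=True) == (
            date(2015, 3, 4),
            date(2015, 3, 10),
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.dates(date(1990, 1, 1), date(2030, 1, 1)), st.integers(1, 400), st.booleans())
    def test_window_length_is_exactly_n_days(self, d, n, incl):
        start, end = exposure_window(d.isoformat(), n, incl)
        assert (end - start).days + 1 == n

    def test_nonpositive_window_rejected(self):
        with pytest.raises(QueryError):
            exposure_window("2015-03-10", 0)


def _random_graph(rnd: random.Random, n: int) -> Graph:
    g = Graph()
    for _ in range(n):
        g.add(
            Triple(
                Iri(f"http://e.org/s{rnd.randrange(6)}"),
                Iri(f"http://e.org/p{rnd.randrange(4)}"),
                rnd.choice(
                    [
                        Iri(f"http://e.org/s{rnd.randrange(6)}"),
                        TypedLiteral(str(rnd.randrange(5)), XSD.integer),
                    ]
                ),
            )
        )
    return g


def _random_spec(rnd: random.Random) -> QuerySpec:
    vars_pool = ["a", "b", "c"]

    def term(pos):
        r = rnd.random()
        if r < 0.5:
            return Var(rnd.choice(vars_pool))
        if pos == "p":
            return Iri(f"http://e.org/p{rnd.randrange(4)}")
        return Iri(f"http://e.org/s{rnd.randrange(6)}")

    patterns = [TriplePattern(term("s"), term("p"), term("o")) for _ in range(rnd.randint(1, 3))]
    return QuerySpec(patterns=patterns)


def _nested_loop_oracle(g: Graph, spec: QuerySpec):
    """Naive oracle: try every assignment of triples to patterns."""
    triples = list(g)
    results = set()
    names = sorted({v for p in spec.patterns for v in p.variables()})
    for combo in itertools.product(triples, repeat=len(spec.patterns)):
        binding = {}
        ok = True
        for pat, t in zip(spec.patterns, combo):
            for pt, tt in ((pat.subject, t.subject), (pat.predicate, t.predicate), (pat.object, t.object)):
                if isinstance(pt, Var):
                    if pt.name in binding and binding[pt.name] != tt:
                        ok = False
                        break
                    binding[pt.name] = tt
                elif pt != tt:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            results.add(tuple(binding[n] for n in names))
    return sorted(results, key=lambda row: tuple(str(x) for x in row))


class TestEvaluate:
    def test_join_on_shared_variable_matches_oracle(self):
        g = Graph(
            [
                Triple(Iri("http://e.org/s1"), Iri("http://e.org/p0"), Iri("http://e.org/s2")),
                Triple(Iri("http://e.org/s1"), Iri("http://e.org/p1"), TypedLiteral("3", XSD.integer)),
                Triple(Iri("http://e.org/s2"), Iri("http://e.org/p1"), TypedLiteral("4", XSD.integer)),
            ]
        )
        spec = QuerySpec(
            patterns=[
                parse_pattern("?s http://e.org/p0 ?o"),
                parse_pattern("?s http://e.org/p1 ?v"),
            ]
        )
        got = [(b["o"], b["s"], b["v"]) for b in evaluate(g, spec)]
        assert got == _nested_loop_oracle(g, spec)

    def test_contradictory_date_range_is_empty(self):
        g = Graph([Triple(Iri("http://e.org/s1"), AVERT.diagnosisDate, TypedLiteral("2016-02-01", XSD.date))])
        spec = QuerySpec(
            patterns=[TriplePattern(Var("p"), AVERT.diagnosisDate, Var("d"))],
            filters=[DateRange("d", date(2016, 3, 1), date(2016, 1, 1))],
        )
        assert evaluate(g, spec) == []

    def test_unknown_projection_variable_rejected(self):
        with pytest.raises(QueryError):
            QuerySpec(patterns=[TriplePattern(Var("s"), RDF.type, AVERT.Patient)], projection=["zz"])

    def test_matches_nested_loop_oracle_on_random_pairs(self):
        rnd = random.Random(99)
        for _ in range(200):
            g = _random_graph(rnd, rnd.randint(0, 25))
            spec = _random_spec(rnd)
            names = sorted({v for p in spec.patterns for v in p.variables()})
            got = [tuple(b[n] for n in names) for b in evaluate(g, spec)]
            assert got == _nested_loop_oracle(g, spec)

    def test_filters_commute(self):
        rnd = random.Random(5)
        g = Graph()
        for i in range(20):
            p = Iri(f"http://e.org/pt{i}")
            g.add(Triple(p, RDF.type, AVERT.Patient))
            g.add(Triple(p, AVERT.diagnosisDate, TypedLiteral(f"2016-01-{(i % 28) + 1:02d}", XSD.date)))
            if i % 3 == 0:
                g.add(Triple(p, AVERT.comorbidity, TypedLiteral("diabetes", XSD.string)))
        filters = [
            DateRange("d", date(2016, 1, 5), date(2016, 1, 25)),
            ExcludeHasTriple("p", AVERT.comorbidity, TypedLiteral("diabetes", XSD.string)),
            WeekEquals("d", IsoWeek(2016, 2)),
        ]
        base_spec = lambda fs: QuerySpec(
            patterns=[
                TriplePattern(Var("p"), RDF.type, AVERT.Patient),
                TriplePattern(Var("p"), AVERT.diagnosisDate, Var("d")),
            ],
            filters=list(fs),
            projection=["p", "d"],
        )
        reference = evaluate(g, base_spec(filters))
        assert reference  # non-trivial
        for perm in itertools.permutations(filters):
            assert evaluate(g, base_spec(perm)) == reference


class TestFederatedExemplar:
    def test_patient_station_observation_join_count(self, enriched_graph):
        """Patients ⋈ nearest station ⋈ that station's observations in a
        date window, excluding a comorbidity — row count equals a
        hand-computed count over the same graph contents."""
        g = enriched_graph.copy()
        # plant a comorbidity on two patients
        patients = g.subjects_of_type(AVERT.Patient)
        excluded = patients[:2]
        for p in excluded:
            g.add(Triple(p, AVERT.comorbidity, TypedLiteral("asthma", XSD.string)))
        window = (date(2016, 1, 10), date(2016, 1, 16))
        spec = QuerySpec(
            patterns=[
                TriplePattern(Var("p"), RDF.type, AVERT.Patient),
                TriplePattern(Var("p"), AVERT.nearestStation, Var("s")),
                TriplePattern(Var("o"), AVERT.station, Var("s")),
                TriplePattern(Var("o"), AVERT.date, Var("d")),
            ],
            filters=[
                DateRange("d", *window),
                ExcludeHasTriple("p", AVERT.comorbidity, TypedLiteral("asthma", XSD.string)),
            ],
            projection=["p", "o"],
        )
        rows = evaluate(g, spec)
        # hand count: every kept patient pairs with each in-window
        # observation of its nearest station (one observation per day)
        expected = 0
        for p in patients:
            if p in excluded:
                continue
            station = g.value(p, AVERT.nearestStation)
            n_obs = sum(
                1
                for t in g.triples_with_predicate(AVERT.station)
                if t.object == station
                and window[0] <= date.fromisoformat(g.value(t.subject, AVERT.date).lexical) <= window[1]
            )
            expected += n_obs
        assert expected > 0
        assert len(rows) == expected


class TestLinkWeeklyCounts:
    def _graph(self):
        g = Graph()
        r = Iri("http://data.avert.ie/region/LHO_00")
        rec = Iri("http://data.avert.ie/weekly_count/LHO_00/2016-W02")
        g.add(Triple(rec, RDF.type, AVERT.WeeklyCount))
        g.add(Triple(rec, AVERT.region, r))
        g.add(Triple(rec, AVERT.isoWeek, TypedLiteral("2016-W02", XSD.string)))
        g.add(Triple(rec, AVERT.count, TypedLiteral("17", XSD.integer)))
        p = Iri("http://data.avert.ie/patient/P1")
        g.add(Triple(p, RDF.type, AVERT.Patient))
        g.add(Triple(p, AVERT.withinRegion, r))
        g.add(Triple(p, AVERT.diagnosisDate, TypedLiteral("2016-01-12", XSD.date)))  # ISO 2016-W02
        return g, p

    def test_matching_week_count_attached(self):
        g, p = self._graph()
        link_weekly_counts(g)
        assert g.value(p, AVERT.diagnosisWeekCount) == TypedLiteral("17", XSD.integer)

    def test_no_matching_record_adds_nothing(self):
        g, p = self._graph()
        g.add(Triple(p, AVERT.diagnosisDate, TypedLiteral("2017-06-01", XSD.date)))
        g2 = Graph(list(g))
        # patient has two diagnosis dates now; rebuild with only the unmatched one
        g3, p3 = self._graph()
        g3 = Graph([t for t in g3 if t.object != TypedLiteral("2016-01-12", XSD.date)])
        g3.add(Triple(p3, AVERT.diagnosisDate, TypedLiteral("2017-06-01", XSD.date)))
        before = len(g3)
        link_weekly_counts(g3)
        assert len(g3) == before

    def test_idempotent_rerun(self):
        g, _ = self._graph()
        link_weekly_counts(g)
        size = len(g)
        link_weekly_counts(g)
        assert len(g) == size

    def test_duplicate_region_week_records_rejected(self):
        g, _ = self._graph()
        dup = Iri("http://data.avert.ie/weekly_count/LHO_00/dup")
        g.add(Triple(dup, RDF.type, AVERT.WeeklyCount))
        g.add(Triple(dup, AVERT.region, Iri("http://data.avert.ie/region/LHO_00")))
        g.add(Triple(dup, AVERT.isoWeek, TypedLiteral("2016-W02", XSD.string)))
        g.add(Triple(dup, AVERT.count, TypedLiteral("99", XSD.integer)))
        with pytest.raises(QueryError, match="duplicate"):
            link_weekly_counts(g)

    def test_fixture_weekly_count_equals_hidden_daily_sums(self, bundle):
        """Construction identity: each weekly count is the sum of the
        hidden daily incidence series for that region and week."""
        daily = bundle.answers["daily_incidence"].rows
        sums = {}
        for row in daily:
            wk = str(iso_week_of(row["date"]))
            key = (row["region_id"], wk)
            sums[key] = sums.get(key, 0) + int(row["cases"])
        for row in bundle.weekly_counts.rows:
            assert int(row["count"]) == sums[(row["region_id"], row["week"])]
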