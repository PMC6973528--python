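"""Conjunctive triple-pattern queries with temporal/spatial filters.

Covers the three exemplar query classes over the enriched graph:
geographical (region containment), temporo-spatial (records in a region
over a date range) and federated (patients ⋈ nearest station ⋈
observations with a pre-diagnosis window and comorbidity exclusion).
Evaluation is a natural join of per-pattern match sets on shared
variables, then filters, then projection; the result order is sorted,
so identical inputs give identical binding tables.

Weekly surveillance counts (reported per region per week) are
reconciled with daily diagnosis dates through the ISO-8601 week
calendar by default; US CDC epidemiological weeks (Sunday start) are
available as a stated non-default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Literal, Sequence

from .geo import WktPoint, haversine_km, parse_wkt_point, point_in_polygon
from .namespaces import AVERT, GEO, XSD
from .rdf_core import Graph, Iri, Term, Triple, TriplePattern, TypedLiteral, Var, match

__all__ = [
    "QueryError",
    "IsoWeek",
    "Filter",
    "DateRange",
    "WithinRegion",
    "WithinRadius",
    "ExcludeHasTriple",
    "WeekEquals",
    "QuerySpec",
    "evaluate",
    "iso_week_of",
    "exposure_window",
    "link_weekly_counts",
]


class QueryError(Exception):
    pass


@dataclass(frozen=True, order=True)
class IsoWeek:
    """A week of the ISO-8601 week-numbering calendar."""

    year: int
    week: int

    def __post_init__(self):
        if not 1 <= self.week <= 53:
            raise QueryError(f"week out of range: {self.week}")
        # week 53 exists only in long years
        try:
            date.fromisocalendar(self.year, self.week, 1)
        except ValueError:
            raise QueryError(f"no week {self.week} in ISO year {self.year}") from None

    def __str__(self) -> str:
        return f"{self.year}-W{self.week:02d}"

    @classmethod
    def parse(cls, text: str) -> "IsoWeek":
        try:
            y, w = text.split("-W")
            return cls(int(y), int(w))
        except (ValueError, AttributeError):
            raise QueryError(f"bad ISO week id: {text!r}") from None


def iso_week_of(lexical: str, convention: Literal["iso", "cdc"] = "iso") -> IsoWeek:
    """Week containing a yyyy-MM-dd date.

    ``iso``: ISO-8601 weeks (Monday start, week 1 holds the first
    Thursday). ``cdc``: US epidemiological weeks (Sunday start, week 1
    holds January 4th's week shifted to Sunday) — non-default, provided
    because surveillance systems differ in convention.
    """
    try:
        d = date.fromisoformat(lexical)
    except ValueError:
        raise QueryError(f"invalid date: {lexical!r}") from None
    if convention == "iso":
        iso = d.isocalendar()
        return IsoWeek(iso.year, iso.week)
    if convention == "cdc":
        shifted = d + timedelta(days=1)  # CDC weeks = ISO weeks of date+1
        iso = shifted.isocalendar()
        return IsoWeek(iso.year, iso.week)
    raise QueryError(f"unknown week convention: {convention!r}")


def exposure_window(diagnosis_date: str, n_days: int, include_diagnosis: bool = False) -> tuple[date, date]:
    """Closed date window of length ``n_days`` before diagnosis.

    Default is strictly prior: [diagnosis − n_days, diagnosis − 1].
    With ``include_diagnosis`` the window ends on the diagnosis day
    itself: [diagnosis − n_days + 1, diagnosis]. Either way the window
    spans exactly ``n_days`` days.
    """
    if n_days < 1:
        raise QueryError(f"window length must be ≥ 1, got {n_days}")
    d = date.fromisoformat(diagnosis_date)
    if include_diagnosis:
        return d - timedelta(days=n_days - 1), d
    return d - timedelta(days=n_days), d - timedelta(days=1)


# ---------------------------------------------------------------------------
# filters


@dataclass(frozen=True)
class DateRange:
    """Keep bindings whose ``variable`` (xsd:date literal) lies in the
    closed [start, end] range. end < start yields no rows."""

    variable: str
    start: date
    end: date

    def keep(self, binding: dict[str, Term], graph: Graph) -> bool:
        term = binding[self.variable]
        if not isinstance(term, TypedLiteral):
            return False
        try:
            d = date.fromisoformat(term.lexical)
        except ValueError:
            return False
        return self.start <= d <= self.end


def _point_of(term: Term, graph: Graph) -> WktPoint | None:
    """Resolve a binding to a point: a wktLiteral directly, or an IRI
    with a geo:asWKT literal."""
    if isinstance(term, TypedLiteral):
        try:
            return parse_wkt_point(term.lexical)
        except Exception:
            return None
    obj = graph.value(term, GEO.asWKT)
    if isinstance(obj, TypedLiteral):
        try:
            return parse_wkt_point(obj.lexical)
        except Exception:
            return None
    return None


@dataclass(frozen=True)
class WithinRegion:
    """Keep bindings whose ``variable`` geometry falls inside the
    polygon of ``region`` (a geo.Region)."""

    variable: str
    region: object  # geo.Region

    def keep(self, binding: dict[str, Term], graph: Graph) -> bool:
        p = _point_of(binding[self.variable], graph)
        return p is not None and point_in_polygon(p, self.region.polygon)


@dataclass(frozen=True)
class WithinRadius:
    """Keep bindings whose ``variable`` geometry is ≤ ``radius_km``
    great-circle km from ``centre`` (closed inequality)."""

    variable: str
    centre: WktPoint
    radius_km: float

    def keep(self, binding: dict[str, Term], graph: Graph) -> bool:
        p = _point_of(binding[self.variable], graph)
        return p is not None and haversine_km(self.centre, p) <= self.radius_km


@dataclass(frozen=True)
class ExcludeHasTriple:
    """Drop bindings where (?variable, predicate, object) is asserted —
    e.g. excluding patients with a specific comorbidity."""

    variable: str
    predicate: Iri
    object: Term

    def keep(self, binding: dict[str, Term], graph: Graph) -> bool:
        subject = binding[self.variable]
        if not isinstance(subject, Iri):
            return True
        return Triple(subject, self.predicate, self.object) not in graph


@dataclass(frozen=True)
class WeekEquals:
    """Keep bindings whose ``variable`` date falls in the given ISO week."""

    variable: str
    week: IsoWeek

    def keep(self, binding: dict[str, Term], graph: Graph) -> bool:
        term = binding[self.variable]
        if not isinstance(term, TypedLiteral):
            return False
        try:
            return iso_week_of(term.lexical) == self.week
        except QueryError:
            return False


Filter = DateRange | WithinRegion | WithinRadius | ExcludeHasTriple | WeekEquals


@dataclass
class QuerySpec:
    patterns: list[TriplePattern]
    filters: list[Filter] = field(default_factory=list)
    projection: list[str] = field(default_factory=list)

    def __post_init__(self):
        known = {v for p in self.patterns for v in p.variables()}
        for v in self.projection:
            if v not in known:
                raise QueryError(f"projected variable ?{v} appears in no pattern")
        for f in self.filters:
            if f.variable not in known:
                raise QueryError(f"filtered variable ?{f.variable} appears in no pattern")


def _join(left: list[dict[str, Term]], right: list[dict[str, Term]]) -> list[dict[str, Term]]:
    """Natural join on shared variables (hash join on the shared key)."""
    if not left or not right:
        return []
    shared = sorted(set(left[0]) & set(right[0]))
    index: dict[tuple, list[dict[str, Term]]] = {}
    for r in right:
        index.setdefault(tuple(r[v] for v in shared), []).append(r)
    out = []
    for l in left:
        for r in index.get(tuple(l[v] for v in shared), ()):
            merged = dict(l)
            merged.update(r)
            out.append(merged)
    return out


def _binding_sort_key(binding: dict[str, Term], names: Sequence[str]):
    return tuple(str(binding[n]) for n in names)


def evaluate(graph: Graph, spec: QuerySpec) -> list[dict[str, Term]]:
    """Join the pattern match sets, apply filters, project.

    Returns a sorted list of bindings restricted to the projection
    (or to all variables when the projection is empty). Duplicate
    projected rows are collapsed.
    """
    tables = [match(graph, p) for p in spec.patterns]
    if not tables:
        return []
    result = tables[0]
    for t in tables[1:]:
        result = _join(result, t)
    for f in spec.filters:
        result = [b for b in result if f.keep(b, graph)]
    names = spec.projection or sorted({v for p in spec.patterns for v in p.variables()})
    seen = set()
    projected = []
    for b in result:
        row = {n: b[n] for n in names}
        key = _binding_sort_key(row, names)
        if key not in seen:
            seen.add(key)
            projected.append(row)
    projected.sort(key=lambda b: _binding_sort_key(b, names))
    return projected


# ---------------------------------------------------------------------------
# config-level query specs


def parse_term(text: str, prefixes: dict[str, str] | None = None):
    """One pattern term: ``?var``, a quoted literal (optionally
    ``^^datatype``), a CURIE, or an absolute IRI."""
    from .namespaces import expand_curie

    text = text.strip()
    if text.startswith("?"):
        return Var(text[1:])
    if text.startswith('"'):
        if "^^" in text:
            lex, _, dt = text.rpartition("^^")
            return TypedLiteral(lex.strip()[1:-1], expand_curie(dt.strip(), prefixes))
        return TypedLiteral(text[1:-1], XSD.string)
    return expand_curie(text, prefixes)


def parse_pattern(text: str, prefixes: dict[str, str] | None = None) -> TriplePattern:
    """Parse ``"?s predicate ?o"`` (whitespace-separated; literals may
    contain spaces only in the final object position)."""
    parts = text.strip().split(None, 2)
    if len(parts) != 3:
        raise QueryError(f"pattern needs 3 terms: {text!r}")
    return TriplePattern(*(parse_term(p, prefixes) for p in parts))


def build_query_spec(doc: dict, regions: Sequence = (), prefixes: dict[str, str] | None = None) -> QuerySpec:
    """Build a :class:`QuerySpec` from a parsed YAML/JSON document."""
    patterns = [parse_pattern(p, prefixes) for p in doc.get("patterns", [])]
    region_by_iri = {str(r.id): r for r in regions}
    filters: list[Filter] = []
    for f in doc.get("filters", []):
        kind = f.get("kind")
        if kind == "date_range":
            filters.append(
                DateRange(f["variable"], date.fromisoformat(str(f["start"])), date.fromisoformat(str(f["end"])))
            )
        elif kind == "within_region":
            key = str(f["region"])
            if key not in region_by_iri:
                raise QueryError(f"unknown region {key!r} (supply a boundaries file)")
            filters.append(WithinRegion(f["variable"], region_by_iri[key]))
        elif kind == "within_radius":
            from .geo import parse_wkt_point as _pwp

            filters.append(WithinRadius(f["variable"], _pwp(f["centre"]), float(f["radius_km"])))
        elif kind == "exclude_has_triple":
            filters.append(
                ExcludeHasTriple(f["variable"], parse_term(f["predicate"], prefixes), parse_term(f["object"], prefixes))
            )
        elif kind == "week_equals":
            filters.append(WeekEquals(f["variable"], IsoWeek.parse(str(f["week"]))))
        else:
            raise QueryError(f"unknown filter kind: {kind!r}")
    return QuerySpec(patterns=patterns, filters=filters, projection=list(doc.get("projection", [])))


# ---------------------------------------------------------------------------
# weekly surveillance linkage


def link_weekly_counts(
    graph: Graph,
    patients: Sequence[Iri] | None = None,
    count_type: Iri | None = None,
    convention: Literal["iso", "cdc"] = "iso",
    recorder=None,
) -> Graph:
    """Attach the regional infection count for each patient's diagnosis week.

    Weekly count records (typed ``avert:WeeklyCount`` by default) carry
    ``avert:region``, ``avert:isoWeek`` ("yyyy-Www") and ``avert:count``.
    For each patient with ``avert:withinRegion`` and
    ``avert:diagnosisDate``, the matching (region, week) count is added
    as ``avert:diagnosisWeekCount``; patients with no matching record
    get nothing. Duplicate (region, week) records are a data error.
    Idempotent.
    """
    if patients is None:
        patients = graph.subjects_of_type(AVERT.Patient)
    count_type = count_type or AVERT.WeeklyCount
    counts: dict[tuple[Iri, str], TypedLiteral] = {}
    seen_records: dict[tuple[Iri, str], Iri] = {}
    for rec in graph.subjects_of_type(count_type):
        region = graph.value(rec, AVERT.region)
        week = graph.value(rec, AVERT.isoWeek)
        count = graph.value(rec, AVERT.count)
        if not isinstance(region, Iri) or week is None or count is None:
            continue
        key = (region, week.lexical)
        if key in seen_records and seen_records[key] != rec:
            raise QueryError(f"duplicate weekly count records for region {region}, week {week.lexical}")
        seen_records[key] = rec
        counts[key] = count if isinstance(count, TypedLiteral) else TypedLiteral(str(count), XSD.integer)
    linked: list[Iri] = []
    for patient in patients:
        region = graph.value(patient, AVERT.withinRegion)
        diagnosis = graph.value(patient, AVERT.diagnosisDate)
        if not isinstance(region, Iri) or not isinstance(diagnosis, TypedLiteral):
            continue
        week = iso_week_of(diagnosis.lexical, convention)
        count = counts.get((region, str(week)))
        if count is None:
            continue
        graph.add(Triple(patient, AVERT.diagnosisWeekCount, count))
        linked.append(patient)
    if recorder is not None:
        recorder.record_enrichment(
            graph,
            name="weekly-counts",
            used=sorted({r for r, _ in counts}, key=str),
            subjects=linked,
            predicates=[AVERT.diagnosisWeekCount],
        )
    return graph
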