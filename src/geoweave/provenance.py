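"""PROV-style provenance recording for enrichment and projection runs.

Every derivation step (spatial-link materialization, weekly-count
linkage, downlift) is recorded as a ``prov:Activity`` with start/end
timestamps, an associated agent, the entities it used and the entities
it generated. Generated entities are reified at batch granularity: one
entity IRI per enrichment run, linked to the subjects it covered via
``prov:hadMember`` and to the predicates it materialized via
``avert:materializesPredicate``. This keeps the provenance subgraph
linear in the number of enriched resources while still letting
`validate_provenance` flag any enrichment triple that no recorded run
can account for.
"""

from __future__ import annotations

import getpass
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from urllib.parse import quote

from .namespaces import AVERT, DATA, PROV, RDF, XSD
from .rdf_core import Graph, Iri, Triple, TypedLiteral

__all__ = ["ProvenanceError", "ProvActivity", "record_activity", "validate_provenance", "ProvRecorder"]

#: Predicates whose triples are derived (not uplifted from source data)
#: and therefore must be covered by a generating activity.
ENRICHMENT_PREDICATES = (
    AVERT.nearestStation,
    AVERT.nearestStationDistanceKm,
    AVERT.withinRegion,
    AVERT.diagnosisWeekCount,
)


class ProvenanceError(Exception):
    pass


@dataclass(frozen=True)
class ProvActivity:
    id: Iri
    started: str  # xsd:dateTime lexical
    ended: str
    agent: Iri
    used: tuple[Iri, ...] = ()
    generated: tuple[Iri, ...] = ()

    def __post_init__(self):
        if datetime.fromisoformat(self.ended) < datetime.fromisoformat(self.started):
            raise ProvenanceError(f"activity {self.id} ended before it started")


def record_activity(graph: Graph, activity: ProvActivity) -> Graph:
    """Write the activity into the graph.

    Adds 4 core triples (rdf:type, prov:startedAtTime, prov:endedAtTime,
    prov:wasAssociatedWith) plus one ``prov:used`` per input entity and
    one ``entity prov:wasGeneratedBy activity`` per output entity —
    4 + |used| + |generated| in total. A re-used activity id is an error.
    """
    existing = Triple(activity.id, RDF.type, PROV.Activity)
    if existing in graph:
        raise ProvenanceError(f"duplicate activity id: {activity.id}")
    graph.add(existing)
    graph.add(Triple(activity.id, PROV.startedAtTime, TypedLiteral(activity.started, XSD.dateTime)))
    graph.add(Triple(activity.id, PROV.endedAtTime, TypedLiteral(activity.ended, XSD.dateTime)))
    graph.add(Triple(activity.id, PROV.wasAssociatedWith, activity.agent))
    for entity in activity.used:
        graph.add(Triple(activity.id, PROV.used, entity))
    for entity in activity.generated:
        graph.add(Triple(entity, PROV.wasGeneratedBy, activity.id))
    return graph


def validate_provenance(graph: Graph) -> list[Triple]:
    """Enrichment triples lacking a generating activity.

    A triple (s, p, o) with an enrichment predicate p is accounted for
    when some batch entity b satisfies: (b, prov:hadMember, s),
    (b, avert:materializesPredicate, p) and (b, prov:wasGeneratedBy, a)
    for an activity a typed prov:Activity. An empty report means the
    graph is fully provenanced.
    """
    activities = set(graph.subjects_of_type(PROV.Activity))
    generated_by = {}
    for t in graph.triples_with_predicate(PROV.wasGeneratedBy):
        if t.object in activities:
            generated_by.setdefault(t.subject, set()).add(t.object)
    covered: set[tuple[Iri, Iri]] = set()  # (subject, predicate) pairs
    members: dict[Iri, set[Iri]] = {}
    for t in graph.triples_with_predicate(PROV.hadMember):
        members.setdefault(t.subject, set()).add(t.object)
    for t in graph.triples_with_predicate(AVERT.materializesPredicate):
        batch, pred = t.subject, t.object
        if batch not in generated_by or not isinstance(pred, Iri):
            continue
        for subject in members.get(batch, ()):
            covered.add((subject, pred))
    violations = []
    for pred in ENRICHMENT_PREDICATES:
        for t in graph.triples_with_predicate(pred):
            if (t.subject, pred) not in covered:
                violations.append(t)
    return sorted(violations, key=Triple.sort_key)


class ProvRecorder:
    """Mints activity/entity IRIs and timestamps deterministically.

    Real wall-clock timestamps would break byte-identical re-runs, so
    the recorder uses a fixed logical clock advanced by one second per
    recorded activity; pass ``clock_start`` to anchor it. The agent
    defaults to the OS user, minted under ``http://data.avert.ie/agent/``.
    """

    def __init__(self, agent: str | None = None, clock_start: str = "2019-01-01T00:00:00+00:00"):
        name = agent or getpass.getuser()
        self.agent = Iri("http://data.avert.ie/agent/" + quote(name, safe="()"))
        self._clock = datetime.fromisoformat(clock_start)
        self._counter = 0

    def _next_times(self) -> tuple[str, str]:
        start = self._clock
        end = start + timedelta(seconds=1)
        self._clock = end
        return start.isoformat(), end.isoformat()

    def record_enrichment(
        self,
        graph: Graph,
        name: str,
        used: list[Iri],
        subjects: list[Iri],
        predicates: list[Iri],
    ) -> ProvActivity:
        """Record one enrichment batch: the activity, its batch entity,
        and the per-subject/per-predicate coverage triples."""
        self._counter += 1
        activity_id = Iri(f"http://data.avert.ie/activity/{name}/{self._counter}")
        batch = Iri(f"http://data.avert.ie/entity/{name}/{self._counter}")
        started, ended = self._next_times()
        activity = ProvActivity(
            id=activity_id,
            started=started,
            ended=ended,
            agent=self.agent,
            used=tuple(dict.fromkeys(used)),
            generated=(batch,),
        )
        record_activity(graph, activity)
        graph.add(Triple(batch, RDF.type, PROV.Entity))
        for pred in predicates:
            graph.add(Triple(batch, AVERT.materializesPredicate, pred))
        for s in subjects:
            graph.add(Triple(batch, PROV.hadMember, s))
        return activity
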