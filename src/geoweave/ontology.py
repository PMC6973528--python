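"""The bespoke vocabulary, declared as a small RDFS graph.

Patients, stations, observations and weekly surveillance counts get
classes under the ``avert:`` namespace; generic concepts reuse FOAF
(people attributes), GeoSPARQL (features/geometry) and PROV
(activities). The CLI can write this graph alongside the data so a
consumer of the N-Triples output can resolve every term used.
"""

from __future__ import annotations

from .namespaces import AVERT, RDF, RDFS, XSD
from .rdf_core import Graph, Iri, Triple, TypedLiteral

_CLASSES = {
    "Patient": "A de-identified study subject located at a townland centroid",
    "WeatherStation": "A fixed observing station with a WGS84 point location",
    "WeatherObservation": "One station-day record of weather variables",
    "WeeklyCount": "A regional weekly infectious-disease count",
    "Region": "A reporting region bounded by a polygon",
}

_PROPERTIES = {
    "dateOfBirth": "Patient date of birth (xsd:date)",
    "diagnosisDate": "Date of diagnosis, the anchor of the exposure window",
    "townland": "De-identified address label",
    "station": "Observation → station link",
    "date": "Observation date (xsd:date)",
    "temperature": "Daily temperature, °C",
    "rain": "Daily rainfall, mm",
    "region": "Weekly count → region link",
    "isoWeek": "ISO-8601 week identifier, yyyy-Www",
    "count": "Weekly case count (xsd:integer)",
    "nearestStation": "Derived: great-circle-nearest weather station",
    "nearestStationDistanceKm": "Derived: distance to that station, km",
    "withinRegion": "Derived: region containing the patient point",
    "diagnosisWeekCount": "Derived: regional count in the diagnosis week",
    "materializesPredicate": "Provenance: predicate a batch entity covers",
}


def ontology_graph() -> Graph:
    """Class and property declarations with human-readable labels."""
    g = Graph()
    for name, comment in _CLASSES.items():
        iri = AVERT.term(name)
        g.add(Triple(iri, RDF.type, RDFS.Class))
        g.add(Triple(iri, RDFS.comment, TypedLiteral(comment, XSD.string)))
    for name, comment in _PROPERTIES.items():
        iri = AVERT.term(name)
        g.add(Triple(iri, RDF.type, RDF.Property))
        g.add(Triple(iri, RDFS.comment, TypedLiteral(comment, XSD.string)))
    return g
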