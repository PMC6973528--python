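"""Namespace prefix table and CURIE expansion.

All identifiers in the graph are absolute IRIs; prefixed names (CURIEs)
are a convenience accepted at configuration boundaries only and expanded
eagerly, never stored.
"""

from __future__ import annotations

from .rdf_core import Iri

#: Default prefix table. ``avert:`` is the study's bespoke vocabulary for
#: clinical/environmental concepts not covered by FOAF or GeoSPARQL;
#: ``data:`` roots the minted resource identifiers.
DEFAULT_PREFIXES: dict[str, str] = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
    "foaf": "http://xmlns.com/foaf/0.1/",
    "geo": "http://www.opengis.net/ont/geosparql#",
    "prov": "http://www.w3.org/ns/prov#",
    "avert": "http://data.avert.ie/avert#",
    "data": "http://data.avert.ie/",
}


def expand_curie(name: str, prefixes: dict[str, str] | None = None) -> Iri:
    """Expand ``prefix:local`` to an absolute :class:`Iri`.

    Strings that already look like absolute IRIs (contain ``://``) pass
    through unchanged. Unknown prefixes raise ``ValueError``.
    """
    table = DEFAULT_PREFIXES if prefixes is None else prefixes
    if "://" in name:
        return Iri(name)
    prefix, sep, local = name.partition(":")
    if not sep:
        raise ValueError(f"not a CURIE or absolute IRI: {name!r}")
    if prefix not in table:
        raise ValueError(f"unknown prefix {prefix!r} in {name!r}")
    return Iri(table[prefix] + local)


class NS:
    """Attribute-style access to a namespace: ``XSD.date`` etc."""

    def __init__(self, base: str):
        self._base = base

    def __getattr__(self, local: str) -> Iri:
        if local.startswith("_"):
            raise AttributeError(local)
        return Iri(self._base + local)

    def term(self, local: str) -> Iri:
        return Iri(self._base + local)


RDF = NS(DEFAULT_PREFIXES["rdf"])
RDFS = NS(DEFAULT_PREFIXES["rdfs"])
XSD = NS(DEFAULT_PREFIXES["xsd"])
FOAF = NS(DEFAULT_PREFIXES["foaf"])
GEO = NS(DEFAULT_PREFIXES["geo"])
PROV = NS(DEFAULT_PREFIXES["prov"])
AVERT = NS(DEFAULT_PREFIXES["avert"])
DATA = NS(DEFAULT_PREFIXES["data"])
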