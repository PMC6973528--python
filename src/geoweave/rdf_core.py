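"""In-memory RDF triple graph with typed literals.

The graph is the integration substrate for the whole pipeline: every
source table is uplifted into it, every enrichment writes into it, and
the analytic table is projected back out of it. Scope is deliberately
narrow — IRIs and typed literals only (no blank nodes, no named graphs),
set semantics, basic triple-pattern matching, and N-Triples as the one
serialization format. Everything that yields a sequence yields it in a
deterministic sorted order so that runs are byte-reproducible.

Literal equality is (lexical form, datatype IRI) pair equality: "1.0"
and "1.00" are distinct terms even though they denote the same double.
This keeps serialize/parse round-trips exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Iterator, Union

__all__ = [
    "RdfError",
    "ValidationError",
    "ParseError",
    "Iri",
    "TypedLiteral",
    "Triple",
    "Var",
    "TriplePattern",
    "Graph",
    "match",
    "serialize_ntriples",
    "parse_ntriples",
]

_XSD = "http://www.w3.org/2001/XMLSchema#"
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


class RdfError(Exception):
    """Base class for graph-layer errors."""


class ValidationError(RdfError):
    """A term or triple violates its well-formedness contract."""


class ParseError(RdfError):
    """Malformed N-Triples input; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True, order=True)
class Iri:
    """An absolute IRI used as a name for a resource.

    Equality is exact string equality; no normalization is performed.
    """

    value: str

    def __post_init__(self):
        v = self.value
        if not v:
            raise ValidationError("IRI must be non-empty")
        if any(c.isspace() for c in v):
            raise ValidationError(f"IRI contains whitespace: {v!r}")
        if ":" not in v:
            raise ValidationError(f"IRI lacks a scheme: {v!r}")

    def __str__(self) -> str:
        return self.value


def _check_lexical(lexical: str, datatype: str) -> None:
    """Validate a lexical form against the datatypes the pipeline emits."""
    if datatype == _XSD + "date":
        if not _DATE_RE.match(lexical):
            raise ValidationError(f"xsd:date must be yyyy-MM-dd: {lexical!r}")
        try:
            date.fromisoformat(lexical)
        except ValueError:
            raise ValidationError(f"invalid calendar date: {lexical!r}") from None
    elif datatype == _XSD + "dateTime":
        try:
            datetime.fromisoformat(lexical)
        except ValueError:
            raise ValidationError(f"invalid xsd:dateTime: {lexical!r}") from None
    elif datatype in (_XSD + "double", _XSD + "decimal", _XSD + "float"):
        try:
            float(lexical)
        except ValueError:
            raise ValidationError(f"invalid numeric lexical: {lexical!r}") from None
    elif datatype == _XSD + "integer":
        try:
            int(lexical)
        except ValueError:
            raise ValidationError(f"invalid xsd:integer: {lexical!r}") from None
    # other datatypes (xsd:string, geo:wktLiteral, ...) accept any lexical


@dataclass(frozen=True, order=True)
class TypedLiteral:
    """A literal with an explicit datatype IRI.

    Equality (and therefore graph set membership) is on the
    (lexical, datatype) pair — there is no value-space canonicalization.
    """

    lexical: str
    datatype: Iri

    def __post_init__(self):
        _check_lexical(self.lexical, self.datatype.value)

    def __str__(self) -> str:
        return f'"{self.lexical}"^^{self.datatype}'


Term = Union[Iri, TypedLiteral]


@dataclass(frozen=True, order=True)
class Triple:
    subject: Iri
    predicate: Iri
    object: Term

    def __post_init__(self):
        if not isinstance(self.subject, Iri):
            raise ValidationError(f"subject must be an IRI, got {type(self.subject).__name__}")
        if not isinstance(self.predicate, Iri):
            raise ValidationError(f"predicate must be an IRI, got {type(self.predicate).__name__}")
        if not isinstance(self.object, (Iri, TypedLiteral)):
            raise ValidationError(f"object must be an IRI or literal, got {type(self.object).__name__}")

    def sort_key(self) -> tuple[str, str, str]:
        key = getattr(self, "_key", None)
        if key is None:
            key = (_term_token(self.subject), _term_token(self.predicate), _term_token(self.object))
            object.__setattr__(self, "_key", key)
        return key


@dataclass(frozen=True)
class Var:
    """A named variable in a triple pattern (``?s`` style)."""

    name: str

    def __post_init__(self):
        if not self.name or not self.name.replace("_", "").isalnum():
            raise ValidationError(f"bad variable name: {self.name!r}")

    def __str__(self) -> str:
        return "?" + self.name


PatternTerm = Union[Iri, TypedLiteral, Var]


@dataclass(frozen=True)
class TriplePattern:
    subject: PatternTerm
    predicate: PatternTerm
    object: PatternTerm

    def variables(self) -> list[str]:
        out = []
        for t in (self.subject, self.predicate, self.object):
            if isinstance(t, Var) and t.name not in out:
                out.append(t.name)
        return out


class Graph:
    """A set of triples plus a prefix table.

    Re-adding an existing triple is a no-op (set semantics). Iteration
    and serialization are in sorted order.
    """

    def __init__(self, triples: Iterable[Triple] = (), namespaces: dict[str, str] | None = None):
        self._triples: set[Triple] = set()
        self.namespaces: dict[str, str] = dict(namespaces or {})
        self._by_predicate: dict[Iri, set[Triple]] = {}
        # (subject, predicate) → objects; accelerates value()/objects()
        self._sp: dict[tuple[Iri, Iri], set] = {}
        for t in triples:
            self.add(t)

    def add(self, triple: Triple) -> "Graph":
        if not isinstance(triple, Triple):
            raise ValidationError("add() expects a Triple")
        self._triples.add(triple)
        self._by_predicate.setdefault(triple.predicate, set()).add(triple)
        self._sp.setdefault((triple.subject, triple.predicate), set()).add(triple.object)
        return self

    def add_all(self, triples: Iterable[Triple]) -> "Graph":
        for t in triples:
            self.add(t)
        return self

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def __iter__(self) -> Iterator[Triple]:
        return iter(sorted(self._triples, key=Triple.sort_key))

    def __eq__(self, other) -> bool:
        return isinstance(other, Graph) and self._triples == other._triples

    def copy(self) -> "Graph":
        return Graph(self._triples, self.namespaces)

    def triples_with_predicate(self, predicate: Iri) -> list[Triple]:
        return sorted(self._by_predicate.get(predicate, ()), key=Triple.sort_key)

    def objects(self, subject: Iri, predicate: Iri) -> list[Term]:
        return sorted(self._sp.get((subject, predicate), ()), key=_term_token)

    def value(self, subject: Iri, predicate: Iri) -> Term | None:
        objs = self.objects(subject, predicate)
        return objs[0] if objs else None

    def subjects_of_type(self, rdf_type: Iri) -> list[Iri]:
        rdf_type_pred = Iri("http://www.w3.org/1999/02/22-rdf-syntax-ns#type")
        return sorted(
            {t.subject for t in self.triples_with_predicate(rdf_type_pred) if t.object == rdf_type},
            key=lambda i: i.value,
        )


def _unify(pattern: TriplePattern, triple: Triple) -> dict[str, Term] | None:
    binding: dict[str, Term] = {}
    for pt, tt in ((pattern.subject, triple.subject), (pattern.predicate, triple.predicate), (pattern.object, triple.object)):
        if isinstance(pt, Var):
            if pt.name in binding and binding[pt.name] != tt:
                return None
            binding[pt.name] = tt
        elif pt != tt:
            return None
    return binding


def match(graph: Graph, pattern: TriplePattern) -> list[dict[str, Term]]:
    """All variable bindings unifying ``pattern`` with the graph.

    Deterministic: results follow the sorted (subject, predicate,
    object) order of the matched triples. A repeated variable in the
    pattern must bind to the same term in every position.
    """
    candidates: Iterable[Triple]
    if isinstance(pattern.predicate, Iri):
        candidates = graph.triples_with_predicate(pattern.predicate)
    else:
        candidates = graph
    out = []
    for t in candidates:
        b = _unify(pattern, t)
        if b is not None:
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# N-Triples serialization

_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}
_UNESCAPES = {"\\": "\\", '"': '"', "n": "\n", "r": "\r", "t": "\t"}


def _escape_literal(s: str) -> str:
    return "".join(_ESCAPES.get(c, c) for c in s)


def _unescape_literal(s: str, line: int) -> str:
    out = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "\\":
            if i + 1 >= len(s):
                raise ParseError("dangling escape in literal", line)
            nxt = s[i + 1]
            if nxt in _UNESCAPES:
                out.append(_UNESCAPES[nxt])
                i += 2
            elif nxt == "u" and i + 6 <= len(s):
                out.append(chr(int(s[i + 2 : i + 6], 16)))
                i += 6
            else:
                raise ParseError(f"unknown escape \\{nxt}", line)
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _term_token(term: Term) -> str:
    if isinstance(term, Iri):
        return f"<{term.value}>"
    return f'"{_escape_literal(term.lexical)}"^^<{term.datatype.value}>'


def serialize_ntriples(graph: Graph) -> str:
    """Serialize to N-Triples, one triple per sorted line (UTF-8 text)."""
    lines = [
        f"{_term_token(t.subject)} {_term_token(t.predicate)} {_term_token(t.object)} ."
        for t in graph
    ]
    return "\n".join(lines) + ("\n" if lines else "")


_LINE_RE = re.compile(
    r"^<(?P<s>[^>]*)>\s+<(?P<p>[^>]*)>\s+"
    r"(?:<(?P<o_iri>[^>]*)>|\"(?P<o_lex>(?:[^\"\\]|\\.)*)\"(?:\^\^<(?P<o_dt>[^>]*)>)?)"
    r"\s+\.\s*$"
)


def parse_ntriples(text: str, namespaces: dict[str, str] | None = None) -> Graph:
    """Parse an N-Triples document; blank and comment lines are skipped."""
    g = Graph(namespaces=namespaces)
    # split on "\n" only: \n and \r are escaped in literals, but other
    # Unicode line boundaries (\x85,  , ...) may appear raw
    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _LINE_RE.match(line)
        if m is None:
            raise ParseError(f"malformed N-Triples line: {raw!r}", lineno)
        try:
            subject = Iri(m.group("s"))
            predicate = Iri(m.group("p"))
            obj: Term
            if m.group("o_iri") is not None:
                obj = Iri(m.group("o_iri"))
            else:
                lex = _unescape_literal(m.group("o_lex"), lineno)
                dt = m.group("o_dt") or _XSD + "string"
                obj = TypedLiteral(lex, Iri(dt))
            g.add(Triple(subject, predicate, obj))
        except ValidationError as e:
            raise ParseError(str(e), lineno) from e
    return g
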