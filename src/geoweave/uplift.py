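"""Declarative table→graph uplift and grid subsetting.

The mapping model is a small R2RML subset: each `TriplesMap` names a
logical table, a subject IRI template, a set of ``rdf:type`` assertions
and a list of predicate/object maps. Object maps may carry a value
transform — date normalization to the xsd:date lexical space or
codebook decoding (e.g. the 0/1 gender encoding of the patient file).
A missing (empty-string) cell skips that single triple, never the whole
row: the source tables are sparse and a blank observation must not
discard the row's other facts.

`subset_grid` is the pre-uplift step for gridded (NetCDF-style) fields:
only cells whose centre falls in a closed bounding box and whose date
falls in a closed range are tabulated, one row per (time, lat, lon).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Mapping, Sequence
from urllib.parse import quote

import numpy as np

from .namespaces import RDF, XSD, expand_curie
from .rdf_core import Graph, Iri, Triple, TypedLiteral, ValidationError

__all__ = [
    "UpliftError",
    "LogicalTable",
    "DateTransform",
    "DecodeTransform",
    "TermTemplate",
    "TriplesMap",
    "GriddedField",
    "normalize_date",
    "decode_code",
    "apply_template",
    "execute_mapping",
    "subset_grid",
    "read_csv_table",
    "load_mapping_config",
]


class UpliftError(Exception):
    pass


@dataclass
class LogicalTable:
    """Tabular source: ordered columns, rows as dicts of strings.

    Empty string means missing. Every row must cover every column.
    """

    columns: list[str]
    rows: list[dict[str, str]]

    def __post_init__(self):
        for i, row in enumerate(self.rows):
            missing = set(self.columns) - set(row)
            if missing:
                raise UpliftError(f"row {i} lacks columns: {sorted(missing)}")


def read_csv_table(path: str | Path) -> LogicalTable:
    """Read an RFC 4180 CSV (UTF-8, header row mandatory)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise UpliftError(f"{path}: missing header row")
        rows = [{k: (v or "") for k, v in row.items()} for row in reader]
    return LogicalTable(columns=list(reader.fieldnames), rows=rows)


# ---------------------------------------------------------------------------
# value transforms

_PATTERN_TOKENS = {"dd": "%d", "MM": "%m", "yyyy": "%Y"}


def _to_strptime(pattern: str) -> str:
    out = pattern
    for token, directive in _PATTERN_TOKENS.items():
        out = out.replace(token, directive)
    return out


def normalize_date(raw: str, input_pattern: str) -> str:
    """Convert a date to the standard yyyy-MM-dd lexical form.

    ``input_pattern`` uses dd/MM/yyyy tokens (e.g. "dd-MM-yyyy").
    Impossible calendar dates are rejected.
    """
    try:
        parsed = datetime.strptime(raw, _to_strptime(input_pattern))
    except ValueError:
        raise UpliftError(f"cannot parse date {raw!r} with pattern {input_pattern!r}") from None
    return parsed.date().isoformat()


def decode_code(raw: str, codebook: Mapping[str, str], policy: str = "error", column: str = "?") -> str:
    """Map a coded value (e.g. Gender "0") to its label ("Female").

    ``policy`` is ``error`` (unmapped codes raise) or ``passthrough``.
    """
    if not codebook:
        raise UpliftError("empty codebook")
    key = str(raw)
    if key in codebook:
        return codebook[key]
    if policy == "passthrough":
        return key
    raise UpliftError(f"unmapped code {raw!r} in column {column!r}")


@dataclass(frozen=True)
class DateTransform:
    input_pattern: str

    def __call__(self, raw: str, column: str) -> str:
        return normalize_date(raw, self.input_pattern)


@dataclass(frozen=True)
class DecodeTransform:
    codebook: Mapping[str, str]
    policy: str = "error"

    def __call__(self, raw: str, column: str) -> str:
        return decode_code(raw, self.codebook, self.policy, column)


# ---------------------------------------------------------------------------
# term templates and triples maps

_PLACEHOLDER_RE = re.compile(r"\{([^{}]+)\}")

#: RFC 3986: unreserved characters pass through (quote() already keeps
#: ALPHA / DIGIT / "-" / "." / "_" / "~"); parentheses are sub-delims
#: and are kept literal, so a station label like "... (AWS)" encodes to
#: "...%20(AWS)".
_IRI_SAFE = "()"


@dataclass(frozen=True)
class TermTemplate:
    """A term constructor with ``{column}`` placeholders."""

    template: str
    term_kind: str  # "iri" | "literal"
    datatype: Iri | None = None
    transform: DateTransform | DecodeTransform | None = None

    def __post_init__(self):
        if self.term_kind not in ("iri", "literal"):
            raise UpliftError(f"bad term_kind: {self.term_kind!r}")
        if self.term_kind == "literal" and self.datatype is None:
            object.__setattr__(self, "datatype", XSD.string)

    def placeholders(self) -> list[str]:
        return _PLACEHOLDER_RE.findall(self.template)


def apply_template(template: TermTemplate, row: Mapping[str, str]):
    """Instantiate the template against one row.

    Returns an :class:`Iri` or :class:`TypedLiteral`, or ``None`` when
    any placeholder cell is empty (the triple is skipped). A column
    absent from the row altogether is a mapping error.
    """
    values = {}
    for col in template.placeholders():
        if col not in row:
            raise UpliftError(f"template references missing column {col!r}")
        raw = row[col]
        if raw == "":
            return None
        values[col] = raw
    if template.term_kind == "iri":
        encoded = {c: quote(v, safe=_IRI_SAFE) for c, v in values.items()}
        out = _PLACEHOLDER_RE.sub(lambda m: encoded[m.group(1)], template.template)
        return Iri(out)
    filled = _PLACEHOLDER_RE.sub(lambda m: values[m.group(1)], template.template)
    if template.transform is not None:
        cols = template.placeholders()
        filled = template.transform(filled, cols[0] if cols else "?")
    try:
        return TypedLiteral(filled, template.datatype)
    except ValidationError as e:
        raise UpliftError(str(e)) from e


@dataclass
class TriplesMap:
    source: str  # logical table name
    subject: TermTemplate
    predicate_object_maps: list[tuple[Iri, TermTemplate]]
    type_assertions: list[Iri] = field(default_factory=list)

    def __post_init__(self):
        if self.subject.term_kind != "iri":
            raise UpliftError("subject template must produce an IRI")
        if not self.predicate_object_maps:
            raise UpliftError("a triples map needs at least one predicate-object map")


def execute_mapping(
    maps: Sequence[TriplesMap],
    tables: Mapping[str, LogicalTable],
    graph: Graph | None = None,
) -> Graph:
    """Run every triples map over its source table into one graph.

    Per row: one subject IRI, one rdf:type triple per type assertion,
    one triple per non-missing object map. Template and transform
    failures are aggregated across rows and reported together with the
    row index. Deterministic, and idempotent under set semantics.
    """
    g = graph if graph is not None else Graph()
    errors: list[str] = []
    for tmap in maps:
        if tmap.source not in tables:
            raise UpliftError(f"no table supplied for source {tmap.source!r}")
        table = tables[tmap.source]
        for i, row in enumerate(table.rows):
            try:
                subject = apply_template(tmap.subject, row)
            except UpliftError as e:
                errors.append(f"{tmap.source}[{i}] subject: {e}")
                continue
            if subject is None:
                errors.append(f"{tmap.source}[{i}] subject: empty key cell")
                continue
            for rdf_type in tmap.type_assertions:
                g.add(Triple(subject, RDF.type, rdf_type))
            for predicate, obj_template in tmap.predicate_object_maps:
                try:
                    obj = apply_template(obj_template, row)
                except UpliftError as e:
                    errors.append(f"{tmap.source}[{i}] {predicate}: {e}")
                    continue
                if obj is None:
                    continue  # missing cell: skip this triple only
                g.add(Triple(subject, predicate, obj))
    if errors:
        raise UpliftError("uplift failed:\n" + "\n".join(errors))
    return g


# ---------------------------------------------------------------------------
# gridded fields


@dataclass
class GriddedField:
    """In-memory model of a (time × lat × lon) gridded variable."""

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    time_axis: list[date]
    values: np.ndarray
    variable_name: str
    units: str = ""

    def __post_init__(self):
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        if self.values.shape != (len(self.time_axis), len(self.lat_axis), len(self.lon_axis)):
            raise UpliftError(
                f"values shape {self.values.shape} does not match axes "
                f"({len(self.time_axis)}, {len(self.lat_axis)}, {len(self.lon_axis)})"
            )
        for ax, name in ((self.lat_axis, "lat"), (self.lon_axis, "lon")):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise UpliftError(f"{name} axis must be strictly increasing")
        if any(b <= a for a, b in zip(self.time_axis, self.time_axis[1:])):
            raise UpliftError("time axis must be strictly increasing")

    def to_xarray(self):
        import xarray as xr

        return xr.DataArray(
            self.values,
            coords={
                "time": [datetime(d.year, d.month, d.day) for d in self.time_axis],
                "lat": self.lat_axis,
                "lon": self.lon_axis,
            },
            dims=("time", "lat", "lon"),
            name=self.variable_name,
            attrs={"units": self.units} if self.units else {},
        )

    @classmethod
    def from_xarray(cls, da) -> "GriddedField":
        times = [np.datetime64(t, "D").astype(object) for t in da["time"].values]
        return cls(
            lat_axis=da["lat"].values,
            lon_axis=da["lon"].values,
            time_axis=times,
            values=np.asarray(da.values),
            variable_name=da.name or "value",
            units=str(da.attrs.get("units", "")),
        )

    def to_netcdf(self, path: str | Path) -> None:
        self.to_xarray().to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path, variable: str | None = None) -> "GriddedField":
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        name = variable or list(ds.data_vars)[0]
        try:
            return cls.from_xarray(ds[name])
        finally:
            ds.close()


def subset_grid(
    field: GriddedField,
    bbox: tuple[float, float, float, float],
    dates: tuple[date, date],
) -> LogicalTable:
    """Tabulate the cells inside a closed bbox and closed date range.

    ``bbox`` is (lon_min, lon_max, lat_min, lat_max); a cell belongs by
    its centre coordinate. Output columns: date, lat, lon, and the
    variable name; NaN values become empty cells. A bbox disjoint from
    the grid yields an empty table.
    """
    lon_min, lon_max, lat_min, lat_max = bbox
    start, end = dates
    if lon_min > lon_max or lat_min > lat_max:
        raise UpliftError(f"invalid bbox: {bbox}")
    if start > end:
        raise UpliftError(f"invalid date range: {dates}")
    t_idx = [i for i, d in enumerate(field.time_axis) if start <= d <= end]
    lat_idx = [i for i, v in enumerate(field.lat_axis) if lat_min <= v <= lat_max]
    lon_idx = [i for i, v in enumerate(field.lon_axis) if lon_min <= v <= lon_max]
    columns = ["date", "lat", "lon", field.variable_name]
    rows = []
    for ti in t_idx:
        d = field.time_axis[ti].isoformat()
        for ai in lat_idx:
            for oi in lon_idx:
                v = field.values[ti, ai, oi]
                rows.append(
                    {
                        "date": d,
                        "lat": repr(float(field.lat_axis[ai])),
                        "lon": repr(float(field.lon_axis[oi])),
                        field.variable_name: "" if np.isnan(v) else repr(float(v)),
                    }
                )
    return LogicalTable(columns=columns, rows=rows)


# ---------------------------------------------------------------------------
# mapping config (YAML)


def _parse_transform(spec: Mapping, codebooks: Mapping[str, Mapping[str, str]]):
    kind = spec.get("kind")
    if kind == "date":
        return DateTransform(spec["pattern"])
    if kind == "decode":
        book = spec.get("codebook")
        if isinstance(book, str):
            if book not in codebooks:
                raise UpliftError(f"unknown codebook {book!r}")
            book = codebooks[book]
        return DecodeTransform(dict(book), spec.get("policy", "error"))
    raise UpliftError(f"unknown transform kind: {kind!r}")


def load_mapping_config(doc: Mapping) -> list[TriplesMap]:
    """Build triples maps from a parsed YAML/JSON mapping document.

    Layout::

        prefixes: {avert: "http://...", ...}   # optional extras
        codebooks: {gender: {"0": Female, "1": Male}}
        maps:
          - source: patients
            subject: "http://data.avert.ie/patient/{patient_id}"
            types: [avert:Patient, geo:Feature]
            properties:
              - {predicate: foaf:gender, column: gender,
                 transform: {kind: decode, codebook: gender}}
              - {predicate: geo:asWKT, template: "POINT ({lon} {lat})",
                 datatype: geo:wktLiteral}
    """
    from .namespaces import DEFAULT_PREFIXES

    prefixes = dict(DEFAULT_PREFIXES)
    prefixes.update(doc.get("prefixes", {}))
    codebooks = doc.get("codebooks", {})
    maps = []
    for m in doc.get("maps", []):
        pom = []
        for p in m.get("properties", []):
            template = p.get("template", "{%s}" % p["column"] if "column" in p else None)
            if template is None:
                raise UpliftError(f"property needs a column or template: {p}")
            datatype = expand_curie(p["datatype"], prefixes) if "datatype" in p else None
            transform = _parse_transform(p["transform"], codebooks) if "transform" in p else None
            kind = p.get("kind", "literal")
            pom.append(
                (
                    expand_curie(p["predicate"], prefixes),
                    TermTemplate(template, kind, datatype, transform),
                )
            )
        maps.append(
            TriplesMap(
                source=m["source"],
                subject=TermTemplate(m["subject"], "iri"),
                predicate_object_maps=pom,
                type_assertions=[expand_curie(t, prefixes) for t in m.get("types", [])],
            )
        )
    return maps
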