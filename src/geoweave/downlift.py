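"""Project the enriched graph back to a per-patient analytic table.

One row per patient (case-level), deterministic by patient IRI. A
column is either a direct patient attribute (the object of a predicate,
copied with its original lexical form) or a window aggregate: the
statistic of one observation variable at the patient's nearest weather
station over the pre-diagnosis exposure window. Copied values keep
their input lexical form bit-exactly; computed aggregates use the
shortest-repr decimal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

from .namespaces import AVERT
from .query import exposure_window
from .rdf_core import Graph, Iri, TypedLiteral

__all__ = [
    "DownliftError",
    "AttributeColumn",
    "WindowAggregateColumn",
    "ProjectionSpec",
    "EnrichedRow",
    "aggregate",
    "build_enriched_table",
    "write_csv",
    "read_csv_rows",
]

NA = None  # missing-value marker in memory; empty cell on disk by default

_AGGREGATES = ("mean", "sum", "min", "max", "count")


class DownliftError(Exception):
    pass


def aggregate(values: Sequence[float | None], kind: str, policy: str = "skip") -> float | None:
    """Aggregate a window of observations with explicit gaps.

    ``policy="skip"`` aggregates over the non-missing values;
    ``"strict"`` returns NA if any value is missing. An empty (or
    all-missing under skip) input is NA — except ``count``, which
    counts non-missing values and is 0 on empty input.
    """
    if kind not in _AGGREGATES:
        raise DownliftError(f"unknown aggregate {kind!r}")
    if policy not in ("skip", "strict"):
        raise DownliftError(f"unknown missing-value policy {policy!r}")
    present = [v for v in values if v is not None]
    if kind == "count":
        return float(len(present))
    if policy == "strict" and len(present) != len(values):
        return NA
    if not present:
        return NA
    if kind == "mean":
        return sum(present) / len(present)
    if kind == "sum":
        return sum(present)
    if kind == "min":
        return min(present)
    return max(present)


@dataclass(frozen=True)
class AttributeColumn:
    """Copy the object of ``predicate`` on the patient (lexical form for
    literals, IRI string for resources); NA when absent."""

    predicate: Iri


@dataclass(frozen=True)
class WindowAggregateColumn:
    """Aggregate ``value_predicate`` over the patient's nearest-station
    observations inside the exposure window."""

    value_predicate: Iri
    kind: str = "mean"
    policy: str = "skip"

    def __post_init__(self):
        if self.kind not in _AGGREGATES:
            raise DownliftError(f"unknown aggregate {self.kind!r}")


@dataclass
class ProjectionSpec:
    columns: list[tuple[str, AttributeColumn | WindowAggregateColumn]]
    window_days: int = 7
    include_diagnosis: bool = False

    def __post_init__(self):
        names = [n for n, _ in self.columns]
        if len(names) != len(set(names)):
            raise DownliftError("duplicate column names in projection")
        if self.window_days < 1:
            raise DownliftError("window must span at least one day")


@dataclass
class EnrichedRow:
    patient: Iri
    cells: dict[str, str | None]  # column name -> lexical value or NA


def _collect_observations(graph: Graph, value_predicate: Iri) -> dict[Iri, list[tuple[date, float | None]]]:
    """All observations carrying ``value_predicate``, grouped by station.

    An observation node has avert:station, avert:date and zero or more
    value predicates; a date with the value predicate absent is a gap.
    """
    by_station: dict[Iri, list[tuple[date, float | None]]] = {}
    for obs in graph.subjects_of_type(AVERT.WeatherObservation):
        station = graph.value(obs, AVERT.station)
        d = graph.value(obs, AVERT.date)
        if not isinstance(station, Iri) or not isinstance(d, TypedLiteral):
            continue
        val = graph.value(obs, value_predicate)
        parsed: float | None
        if isinstance(val, TypedLiteral):
            try:
                parsed = float(val.lexical)
            except ValueError:
                raise DownliftError(f"non-numeric value for {value_predicate} on {obs}") from None
        else:
            parsed = None
        by_station.setdefault(station, []).append((date.fromisoformat(d.lexical), parsed))
    return by_station


def _format_number(x: float) -> str:
    """Shortest decimal representation; integral floats print bare."""
    if x == int(x):
        return str(int(x))
    return repr(x)


def build_enriched_table(
    graph: Graph,
    spec: ProjectionSpec,
    patients: Sequence[Iri] | None = None,
    recorder=None,
) -> list[EnrichedRow]:
    """One enriched row per patient, ordered by patient IRI.

    Requires the spatial enrichment triples (avert:nearestStation) to
    be present for window aggregates to resolve; a patient whose
    station has no in-window observations gets NA cells. Column specs
    referencing unknown aggregate kinds fail before any row is built
    (validated at spec construction).
    """
    if patients is None:
        patients = graph.subjects_of_type(AVERT.Patient)
    patients = sorted(patients, key=lambda i: i.value)
    obs_cache: dict[Iri, dict[Iri, list[tuple[date, float | None]]]] = {}
    for _, col in spec.columns:
        if isinstance(col, WindowAggregateColumn) and col.value_predicate not in obs_cache:
            obs_cache[col.value_predicate] = _collect_observations(graph, col.value_predicate)
    rows = []
    for patient in patients:
        cells: dict[str, str | None] = {}
        diagnosis = graph.value(patient, AVERT.diagnosisDate)
        station = graph.value(patient, AVERT.nearestStation)
        for name, col in spec.columns:
            if isinstance(col, AttributeColumn):
                obj = graph.value(patient, col.predicate)
                if obj is None:
                    cells[name] = NA
                elif isinstance(obj, TypedLiteral):
                    cells[name] = obj.lexical
                else:
                    cells[name] = obj.value
            else:
                if not isinstance(diagnosis, TypedLiteral) or not isinstance(station, Iri):
                    cells[name] = NA
                    continue
                start, end = exposure_window(diagnosis.lexical, spec.window_days, spec.include_diagnosis)
                # chronological order: float sums must not depend on
                # the incidental IRI sort order of observation nodes
                window = [
                    v for d, v in sorted(obs_cache[col.value_predicate].get(station, []), key=lambda t: t[0])
                    if start <= d <= end
                ]
                agg = aggregate(window, col.kind, col.policy)
                cells[name] = NA if agg is None else _format_number(agg)
        rows.append(EnrichedRow(patient=patient, cells=cells))
    if recorder is not None:
        recorder.record_enrichment(
            graph,
            name="downlift",
            used=[p for p in patients],
            subjects=[],
            predicates=[],
        )
    return rows


def write_csv(
    rows: Sequence[EnrichedRow],
    path: str | Path,
    columns: Sequence[str] | None = None,
    na_marker: str = "",
) -> None:
    """RFC 4180 CSV with a ``patient`` id column first; NA cells are
    written as ``na_marker`` (default: empty field)."""
    if columns is None:
        columns = list(rows[0].cells) if rows else []
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["patient", *columns])
            for row in rows:
                writer.writerow(
                    [row.patient.value]
                    + [na_marker if row.cells.get(c) is None else row.cells[c] for c in columns]
                )
    except OSError as e:
        raise DownliftError(f"cannot write {path}: {e}") from e


def read_csv_rows(path: str | Path, na_marker: str = "") -> list[EnrichedRow]:
    """Read back a table written by :func:`write_csv` (round-trip exact)."""
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if not header or header[0] != "patient":
                raise DownliftError(f"{path}: not an enriched table (missing patient column)")
            columns = header[1:]
            rows = []
            for rec in reader:
                cells = {
                    c: (NA if v == na_marker else v) for c, v in zip(columns, rec[1:])
                }
                rows.append(EnrichedRow(patient=Iri(rec[0]), cells=cells))
            return rows
    except OSError as e:
        raise DownliftError(f"cannot read {path}: {e}") from e
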