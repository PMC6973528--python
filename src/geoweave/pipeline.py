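"""Stage orchestration shared by the CLI and the test suite.

The five stages — generate fixtures, uplift, enrich, query, downlift —
are plain functions over paths and graphs so that a monolithic run and
stage-by-stage runs produce identical intermediates.
"""

from __future__ import annotations

import csv
import logging
import time
from pathlib import Path

import yaml

from .downlift import AttributeColumn, ProjectionSpec, WindowAggregateColumn, build_enriched_table, write_csv
from .fixtures import SyntheticConfig, default_mapping_doc, generate, write_bundle
from .geo import Region, RingPolygon, WktPoint, materialize_spatial_links, parse_wkt_polygon
from .namespaces import AVERT, FOAF, RDFS
from .provenance import ProvRecorder, validate_provenance
from .query import link_weekly_counts
from .rdf_core import Graph, Iri, parse_ntriples, serialize_ntriples
from .uplift import execute_mapping, load_mapping_config, read_csv_table

log = logging.getLogger("geoweave")

FIXTURE_TABLES = ("patients", "stations", "observations", "weekly_counts")


def load_regions(path: str | Path) -> list[Region]:
    """Boundary set from CSV (region_id,label,level,wkt) or GeoJSON."""
    path = Path(path)
    if path.suffix == ".geojson" or path.suffix == ".json":
        import json

        doc = json.loads(path.read_text(encoding="utf-8"))
        regions = []
        for feat in doc.get("features", []):
            ring = feat["geometry"]["coordinates"][0]
            pts = [WktPoint(float(x), float(y)) for x, y in ring]
            if pts[0] == pts[-1]:
                pts = pts[:-1]
            props = feat.get("properties", {})
            regions.append(
                Region(
                    id=Iri("http://data.avert.ie/region/" + props["region_id"]),
                    label=props.get("label", props["region_id"]),
                    polygon=RingPolygon(tuple(pts)),
                    level=props.get("level", "county"),
                )
            )
        return regions
    regions = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            regions.append(
                Region(
                    id=Iri("http://data.avert.ie/region/" + row["region_id"]),
                    label=row["label"],
                    polygon=parse_wkt_polygon(row["wkt"]),
                    level=row["level"],
                )
            )
    return regions


def uplift_stage(fixtures_dir: str | Path, mapping_path: str | Path | None = None) -> Graph:
    """Uplift the four fixture tables through the declarative mapping."""
    fixtures_dir = Path(fixtures_dir)
    doc = (
        yaml.safe_load(Path(mapping_path).read_text(encoding="utf-8"))
        if mapping_path is not None
        else default_mapping_doc()
    )
    maps = load_mapping_config(doc)
    tables = {name: read_csv_table(fixtures_dir / f"{name}.csv") for name in FIXTURE_TABLES}
    return execute_mapping(maps, tables)


def enrich_stage(graph: Graph, regions: list[Region], recorder: ProvRecorder) -> Graph:
    """Spatial links then weekly-count linkage, both provenanced."""
    materialize_spatial_links(graph, regions=regions, recorder=recorder)
    link_weekly_counts(graph, recorder=recorder)
    return graph


def default_projection(window_days: int = 7, include_diagnosis: bool = False) -> ProjectionSpec:
    """The standard analytic table: clinical attributes, spatial links,
    diagnosis-week count, and window summaries of temperature/rain."""
    return ProjectionSpec(
        columns=[
            ("gender", AttributeColumn(FOAF.gender)),
            ("date_of_birth", AttributeColumn(AVERT.dateOfBirth)),
            ("diagnosis_date", AttributeColumn(AVERT.diagnosisDate)),
            ("townland", AttributeColumn(AVERT.townland)),
            ("nearest_station", AttributeColumn(AVERT.nearestStation)),
            ("nearest_station_km", AttributeColumn(AVERT.nearestStationDistanceKm)),
            ("region", AttributeColumn(AVERT.withinRegion)),
            ("diagnosis_week_count", AttributeColumn(AVERT.diagnosisWeekCount)),
            ("mean_temperature", WindowAggregateColumn(AVERT.temperature, "mean")),
            ("min_temperature", WindowAggregateColumn(AVERT.temperature, "min")),
            ("max_temperature", WindowAggregateColumn(AVERT.temperature, "max")),
            ("total_rain", WindowAggregateColumn(AVERT.rain, "sum")),
            ("n_temperature_obs", WindowAggregateColumn(AVERT.temperature, "count")),
        ],
        window_days=window_days,
        include_diagnosis=include_diagnosis,
    )


def run_all(
    fixtures_dir: str | Path,
    out_dir: str | Path,
    agent: str = "pipeline",
    window_days: int = 7,
    include_diagnosis: bool = False,
    mapping_path: str | Path | None = None,
) -> dict:
    """Uplift → enrich → downlift over an existing fixture bundle.

    Writes graph_uplift.nt, graph_enriched.nt and enriched.csv under
    ``out_dir``; returns stage statistics. Deterministic: identical
    inputs give byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats: dict = {}

    t0 = time.perf_counter()
    graph = uplift_stage(fixtures_dir, mapping_path)
    (out / "graph_uplift.nt").write_text(serialize_ntriples(graph), encoding="utf-8")
    stats["uplift_triples"] = len(graph)
    log.info("stage=uplift triples=%d duration=%.2fs", len(graph), time.perf_counter() - t0)

    t0 = time.perf_counter()
    regions = load_regions(Path(fixtures_dir) / "boundaries.csv")
    recorder = ProvRecorder(agent=agent)
    enrich_stage(graph, regions, recorder)
    (out / "graph_enriched.nt").write_text(serialize_ntriples(graph), encoding="utf-8")
    stats["enriched_triples"] = len(graph)
    stats["provenance_violations"] = len(validate_provenance(graph))
    log.info("stage=enrich triples=%d duration=%.2fs", len(graph), time.perf_counter() - t0)

    t0 = time.perf_counter()
    spec = default_projection(window_days, include_diagnosis)
    rows = build_enriched_table(graph, spec, recorder=recorder)
    write_csv(rows, out / "enriched.csv", columns=[n for n, _ in spec.columns])
    # provenance of the downlift run itself belongs in the graph file
    (out / "graph_enriched.nt").write_text(serialize_ntriples(graph), encoding="utf-8")
    stats["enriched_rows"] = len(rows)
    log.info("stage=downlift rows=%d duration=%.2fs", len(rows), time.perf_counter() - t0)
    return stats


def generate_stage(out_dir: str | Path, config: SyntheticConfig) -> None:
    bundle = generate(config)
    write_bundle(bundle, out_dir)
    log.info(
        "stage=generate patients=%d stations=%d regions=%d days=%d",
        config.n_patients, config.n_stations, config.n_regions, config.n_days,
    )
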