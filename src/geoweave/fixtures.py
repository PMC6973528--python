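"""Seeded synthetic data emulating the study's dataset shapes.

The generator produces, offline and deterministically, one bundle per
seed containing every input the pipeline consumes:

* a patient table (townland-centroid point per patient, gender coded
  0/1, dates printed dd-MM-yyyy to exercise normalization),
* a weather-station location table and a daily observation table
  (seasonal sinusoid + noise, values blanked at a configurable
  missingness rate — keys are never blanked),
* a weekly regional infection-count table derived by summing a hidden
  daily incidence series, so week-sum consistency is checkable,
* region boundary polygons tiling a lon/lat rectangle near Ireland's
  bounds with no overlap, every patient strictly inside exactly one,
* a gridded pollution field (time × lat × lon).

Alongside the inputs it writes *answer files*: the true nearest
station, true containing region and true exposure-window means per
patient, computed by brute force at generation time with its own
arithmetic (not via the graph pipeline), so every enrichment step can
be scored for exact recovery.

What this emulates — and what it does not: the shapes, granularities
and encodings of real surveillance/weather data are reproduced, but
there is no spatial disease clustering, no station siting bias and no
weather autocorrelation beyond the seasonal cycle, so passing tests
demonstrate mechanical correctness of the linkage, not epidemiological
realism.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .geo import Region, RingPolygon, WktPoint
from .query import iso_week_of
from .rdf_core import Iri
from .uplift import GriddedField, LogicalTable

__all__ = ["FixtureError", "SyntheticConfig", "Bundle", "generate", "write_bundle", "default_mapping_doc"]

#: synthetic rectangle approximating Ireland's bounding box (°E, °N)
LON_MIN, LON_MAX = -11.0, -5.0
LAT_MIN, LAT_MAX = 51.0, 55.5

GENDER_CODEBOOK = {"0": "Female", "1": "Male"}


class FixtureError(Exception):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_regions: int = 6
    n_stations: int = 8
    n_patients: int = 20
    date_start: date = date(2016, 1, 1)
    n_days: int = 90
    grid_lat: int = 10
    grid_lon: int = 10
    missing_rate: float = 0.05
    window_days: int = 7
    include_diagnosis: bool = False
    region_grid: tuple[int, int] | None = None  # explicit (rows, cols) tiling

    def __post_init__(self):
        if min(self.n_regions, self.n_stations, self.n_patients, self.grid_lat, self.grid_lon) < 1:
            raise FixtureError("all counts must be ≥ 1")
        if self.n_days < 14:
            raise FixtureError("date span must cover at least 14 days")
        if not 0.0 <= self.missing_rate < 1.0:
            raise FixtureError("missing_rate must be in [0, 1)")
        if self.region_grid is not None:
            r, c = self.region_grid
            if r * c != self.n_regions:
                raise FixtureError(
                    f"region grid {r}x{c} cannot tile {self.n_regions} regions"
                )

    @property
    def date_end(self) -> date:
        return self.date_start + timedelta(days=self.n_days - 1)


@dataclass
class Bundle:
    config: SyntheticConfig
    patients: LogicalTable
    stations: LogicalTable
    observations: LogicalTable
    weekly_counts: LogicalTable
    boundaries: LogicalTable  # region_iri, label, level, wkt
    regions: list[Region]
    grid: GriddedField
    answers: dict[str, LogicalTable]  # nearest_station, region, window_means, daily_incidence


def _tiling(cfg: SyntheticConfig) -> tuple[int, int]:
    if cfg.region_grid is not None:
        return cfg.region_grid
    n = cfg.n_regions
    for r in range(int(math.isqrt(n)), 0, -1):
        if n % r == 0:
            return r, n // r
    raise FixtureError(f"cannot tile {n} regions")  # unreachable: 1 divides n


def _haversine_vec(lon1, lat1, lons, lats):
    """Brute-force great-circle distances (km) for the answer files;
    kept separate from the geo module on purpose."""
    R = 6371.0088
    p1, p2 = np.radians(lat1), np.radians(lats)
    dphi = p2 - p1
    dlmb = np.radians(lons - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * R * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def _ddmmyyyy(d: date) -> str:
    return d.strftime("%d-%m-%Y")


def generate(config: SyntheticConfig) -> Bundle:
    """Build a complete synthetic bundle; same config ⇒ identical bundle."""
    rng = np.random.default_rng(config.seed)
    rows_n, cols_n = _tiling(config)
    lon_step = (LON_MAX - LON_MIN) / cols_n
    lat_step = (LAT_MAX - LAT_MIN) / rows_n

    regions: list[Region] = []
    boundary_rows = []
    for k in range(config.n_regions):
        r, c = divmod(k, cols_n)
        x0, y0 = LON_MIN + c * lon_step, LAT_MIN + r * lat_step
        poly = RingPolygon(
            (
                WktPoint(x0, y0),
                WktPoint(x0 + lon_step, y0),
                WktPoint(x0 + lon_step, y0 + lat_step),
                WktPoint(x0, y0 + lat_step),
            )
        )
        region_id = f"LHO_{k:02d}"
        region = Region(
            id=Iri(f"http://data.avert.ie/region/{region_id}"),
            label=f"Health region {k:02d}",
            polygon=poly,
            level="lho",
        )
        regions.append(region)
        boundary_rows.append(
            {
                "region_id": region_id,
                "label": region.label,
                "level": region.level,
                "wkt": poly.to_wkt(),
            }
        )
    boundaries = LogicalTable(["region_id", "label", "level", "wkt"], boundary_rows)

    # stations, named with spaces/parentheses to exercise IRI encoding
    station_rows = []
    st_lons = rng.uniform(LON_MIN, LON_MAX, config.n_stations)
    st_lats = rng.uniform(LAT_MIN, LAT_MAX, config.n_stations)
    station_names = [f"Station {i:02d} Automatic Weather Station (AWS)" for i in range(config.n_stations)]
    for i in range(config.n_stations):
        station_rows.append(
            {
                "name": station_names[i],
                "lon": repr(round(float(st_lons[i]), 6)),
                "lat": repr(round(float(st_lats[i]), 6)),
            }
        )
    stations = LogicalTable(["name", "lon", "lat"], station_rows)

    # daily station observations: seasonal sinusoid + noise; values only
    # may go missing, never the (station, date) keys
    obs_rows = []
    for i, name in enumerate(station_names):
        base = rng.normal(9.0, 1.5)  # per-station climate offset, °C
        for dayno in range(config.n_days):
            d = config.date_start + timedelta(days=dayno)
            doy = d.timetuple().tm_yday
            temp = base - 5.0 * math.cos(2 * math.pi * doy / 365.25) + rng.normal(0.0, 2.0)
            rain = float(rng.exponential(2.5))
            temp_lex = f"{temp:.2f}" if rng.random() >= config.missing_rate else ""
            rain_lex = f"{rain:.2f}" if rng.random() >= config.missing_rate else ""
            obs_rows.append(
                {
                    "station": name,
                    "date": _ddmmyyyy(d),
                    "temperature": temp_lex,
                    "rain": rain_lex,
                }
            )
    observations = LogicalTable(["station", "date", "temperature", "rain"], obs_rows)

    # hidden daily incidence per region; weekly counts are its week-sums
    incidence_rows = []
    weekly: dict[tuple[str, str], int] = {}
    for k in range(config.n_regions):
        region_id = f"LHO_{k:02d}"
        for dayno in range(config.n_days):
            d = config.date_start + timedelta(days=dayno)
            cases = int(rng.poisson(3.0))
            incidence_rows.append(
                {"region_id": region_id, "date": d.isoformat(), "cases": str(cases)}
            )
            week = str(iso_week_of(d.isoformat()))
            weekly[(region_id, week)] = weekly.get((region_id, week), 0) + cases
    weekly_rows = [
        {"region_id": rid, "week": wk, "count": str(n)}
        for (rid, wk), n in sorted(weekly.items())
    ]
    weekly_counts = LogicalTable(["region_id", "week", "count"], weekly_rows)
    daily_incidence = LogicalTable(["region_id", "date", "cases"], incidence_rows)

    # patients: strictly inside one region (10% cell margin), diagnosis
    # late enough that the exposure window lies inside the span
    st_lon_arr = np.array([float(r["lon"]) for r in station_rows])
    st_lat_arr = np.array([float(r["lat"]) for r in station_rows])
    patient_rows, ans_station, ans_region, ans_means = [], [], [], []
    obs_by_key = {(r["station"], r["date"]): r for r in obs_rows}
    earliest_diag = config.window_days if not config.include_diagnosis else config.window_days - 1
    for j in range(config.n_patients):
        pid = f"P{j:03d}"
        k = int(rng.integers(0, config.n_regions))
        r, c = divmod(k, cols_n)
        mx, my = 0.1 * lon_step, 0.1 * lat_step
        lon = float(rng.uniform(LON_MIN + c * lon_step + mx, LON_MIN + (c + 1) * lon_step - mx))
        lat = float(rng.uniform(LAT_MIN + r * lat_step + my, LAT_MIN + (r + 1) * lat_step - my))
        lon, lat = round(lon, 6), round(lat, 6)
        dob = config.date_start - timedelta(days=int(rng.integers(20 * 365, 70 * 365)))
        diag_day = int(rng.integers(earliest_diag, config.n_days))
        diag = config.date_start + timedelta(days=diag_day)
        gender = str(int(rng.integers(0, 2)))
        patient_rows.append(
            {
                "patient_id": pid,
                "gender": gender,
                "dob": _ddmmyyyy(dob),
                "diagnosis_date": _ddmmyyyy(diag),
                "lon": repr(lon),
                "lat": repr(lat),
                "townland": f"Townland {j:03d}",
            }
        )
        dists = _haversine_vec(lon, lat, st_lon_arr, st_lat_arr)
        order = sorted(range(config.n_stations), key=lambda i: (dists[i], station_names[i]))
        best = order[0]
        ans_station.append(
            {
                "patient_id": pid,
                "station": station_names[best],
                "distance_km": repr(float(dists[best])),
            }
        )
        ans_region.append({"patient_id": pid, "region_id": f"LHO_{k:02d}"})
        # true window mean of temperature at the true nearest station,
        # recomputed from the printed lexicals (missing values skipped)
        if config.include_diagnosis:
            w0, w1 = diag - timedelta(days=config.window_days - 1), diag
        else:
            w0, w1 = diag - timedelta(days=config.window_days), diag - timedelta(days=1)
        vals = []
        d = w0
        while d <= w1:
            rec = obs_by_key.get((station_names[best], _ddmmyyyy(d)))
            if rec is not None and rec["temperature"] != "":
                vals.append(float(rec["temperature"]))
            d += timedelta(days=1)
        mean_lex = repr(sum(vals) / len(vals)) if vals else ""
        ans_means.append({"patient_id": pid, "mean_temperature": mean_lex})
    patients = LogicalTable(
        ["patient_id", "gender", "dob", "diagnosis_date", "lon", "lat", "townland"],
        patient_rows,
    )

    # gridded pollution field over the same rectangle and span
    glat = np.linspace(LAT_MIN, LAT_MAX, config.grid_lat)
    glon = np.linspace(LON_MIN, LON_MAX, config.grid_lon)
    times = [config.date_start + timedelta(days=i) for i in range(config.n_days)]
    tt = np.arange(config.n_days)[:, None, None]
    la = glat[None, :, None]
    lo = glon[None, None, :]
    values = (
        12.0
        + 4.0 * np.sin(2 * np.pi * tt / 30.0)
        + 0.8 * (la - LAT_MIN)
        + 0.5 * (lo - LON_MIN)
        + rng.normal(0.0, 1.0, (config.n_days, config.grid_lat, config.grid_lon))
    )
    grid = GriddedField(
        lat_axis=glat, lon_axis=glon, time_axis=times, values=values,
        variable_name="pm10", units="ug/m3",
    )

    answers = {
        "nearest_station": LogicalTable(["patient_id", "station", "distance_km"], ans_station),
        "region": LogicalTable(["patient_id", "region_id"], ans_region),
        "window_means": LogicalTable(["patient_id", "mean_temperature"], ans_means),
        "daily_incidence": daily_incidence,
    }
    return Bundle(
        config=config,
        patients=patients,
        stations=stations,
        observations=observations,
        weekly_counts=weekly_counts,
        boundaries=boundaries,
        regions=regions,
        grid=grid,
        answers=answers,
    )


def _write_table(table: LogicalTable, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=table.columns)
        writer.writeheader()
        writer.writerows(table.rows)


def write_bundle(bundle: Bundle, out_dir: str | Path, grid_format: str = "netcdf") -> None:
    """Write the bundle under ``out_dir``: input CSVs, boundary CSV and
    GeoJSON, the gridded field (NetCDF by default), and the answer
    files under ``answers/``. Byte-identical for identical configs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_table(bundle.patients, out / "patients.csv")
    _write_table(bundle.stations, out / "stations.csv")
    _write_table(bundle.observations, out / "observations.csv")
    _write_table(bundle.weekly_counts, out / "weekly_counts.csv")
    _write_table(bundle.boundaries, out / "boundaries.csv")
    features = []
    for region, row in zip(bundle.regions, bundle.boundaries.rows):
        ring = [[p.lon, p.lat] for p in region.polygon.vertices]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {"region_id": row["region_id"], "label": region.label, "level": region.level},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    (out / "boundaries.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1, sort_keys=True),
        encoding="utf-8",
    )
    if grid_format == "netcdf":
        bundle.grid.to_netcdf(out / "grid.nc")
    answers_dir = out / "answers"
    answers_dir.mkdir(exist_ok=True)
    for name, table in bundle.answers.items():
        _write_table(table, answers_dir / f"{name}.csv")


def default_mapping_doc() -> dict:
    """The uplift mapping for the synthetic bundle's four tables,
    mirroring the ontology: patients and stations are geo:Features with
    WKT point geometries; gender decodes through FOAF; all dates are
    normalized to yyyy-MM-dd."""
    return {
        "codebooks": {"gender": GENDER_CODEBOOK},
        "maps": [
            {
                "source": "patients",
                "subject": "http://data.avert.ie/patient/{patient_id}",
                "types": ["avert:Patient", "geo:Feature"],
                "properties": [
                    {"predicate": "foaf:gender", "column": "gender",
                     "transform": {"kind": "decode", "codebook": "gender"}},
                    {"predicate": "avert:dateOfBirth", "column": "dob",
                     "datatype": "xsd:date",
                     "transform": {"kind": "date", "pattern": "dd-MM-yyyy"}},
                    {"predicate": "avert:diagnosisDate", "column": "diagnosis_date",
                     "datatype": "xsd:date",
                     "transform": {"kind": "date", "pattern": "dd-MM-yyyy"}},
                    {"predicate": "geo:asWKT", "template": "POINT ({lon} {lat})",
                     "datatype": "geo:wktLiteral"},
                    {"predicate": "avert:townland", "column": "townland"},
                ],
            },
            {
                "source": "stations",
                "subject": "http://data.avert.ie/weather_station/{name}",
                "types": ["avert:WeatherStation", "geo:Feature"],
                "properties": [
                    {"predicate": "rdfs:label", "column": "name"},
                    {"predicate": "geo:asWKT", "template": "POINT ({lon} {lat})",
                     "datatype": "geo:wktLiteral"},
                ],
            },
            {
                "source": "observations",
                "subject": "http://data.avert.ie/observation/{station}/{date}",
                "types": ["avert:WeatherObservation"],
                "properties": [
                    {"predicate": "avert:station", "kind": "iri",
                     "template": "http://data.avert.ie/weather_station/{station}"},
                    {"predicate": "avert:date", "column": "date",
                     "datatype": "xsd:date",
                     "transform": {"kind": "date", "pattern": "dd-MM-yyyy"}},
                    {"predicate": "avert:temperature", "column": "temperature",
                     "datatype": "xsd:double"},
                    {"predicate": "avert:rain", "column": "rain",
                     "datatype": "xsd:double"},
                ],
            },
            {
                "source": "weekly_counts",
                "subject": "http://data.avert.ie/weekly_count/{region_id}/{week}",
                "types": ["avert:WeeklyCount"],
                "properties": [
                    {"predicate": "avert:region", "kind": "iri",
                     "template": "http://data.avert.ie/region/{region_id}"},
                    {"predicate": "avert:isoWeek", "column": "week"},
                    {"predicate": "avert:count", "column": "count",
                     "datatype": "xsd:integer"},
                ],
            },
        ],
    }
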