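# geoweave

Linking rare-disease patient records to environmental conditions — weather,
pollution, infectious-disease surveillance — is hard because every source
arrives at a different temporal granularity (daily station series, weekly
regional counts) and a different spatial granularity (point coordinates,
administrative regions, lat/lon grids). `geoweave` integrates such sources
through an RDF triple graph: each tabular or gridded input is **uplifted**
into typed triples by a declarative mapping, the graph is **enriched** with
derived temporo-spatial links (nearest weather station, region containment,
diagnosis-week surveillance count), every derivation is recorded as a
PROV-style activity, and the result is **downlifted** back to a per-patient
analytic CSV with exposure-window summaries ready for statistical modelling.

It is aimed at epidemiology / health-informatics groups who need an
auditable, reproducible linkage step between siloed files and their
modelling code — the motivating case being environmental-trigger studies
of very rare autoimmune disease, where cases are too few for classical
case-control designs and every linkage decision must be traceable.

## The core operations

* **Uplift** (R2RML-subset): a mapping document sends each table row to a
  subject IRI template plus predicate–object maps, e.g.
  `⟨data:patient/P007, foaf:gender, "Female"⟩`. Value transforms normalize
  dates to the `xsd:date` lexical space (`dd-MM-yyyy → yyyy-MM-dd`) and
  decode codebooks (`Gender=0 → "Female"`). Empty cells skip single
  triples, never rows.
* **Spatial enrichment**: for patient point *p* and stations *s₁…sₙ*, the
  nearest station is argmin over the haversine great-circle distance
  `d = 2R·asin√(sin²(Δφ/2) + cosφ₁cosφ₂sin²(Δλ/2))`, R = 6371.0088 km;
  region containment uses even-odd ray casting with boundary points inside.
  The links are written back into the graph so later queries need no
  geometry.
* **Temporal reconciliation**: daily diagnosis dates meet weekly
  surveillance counts through the ISO-8601 week calendar; exposure windows
  are the closed interval `[diagnosis − n, diagnosis − 1]` (length exactly
  *n* days; optionally ending on the diagnosis day).
* **Provenance**: each enrichment run is a `prov:Activity` (4 core triples
  + one `prov:used` per input + one `prov:wasGeneratedBy` per output);
  `validate` reports any derived triple no recorded activity accounts for.
* **Downlift**: one row per patient, attribute columns copied bit-exactly,
  window aggregates (mean/sum/min/max/count with skip or strict missing
  policies) computed from the nearest station's observations.

A seeded synthetic-data generator emulates every input shape (patients,
stations, daily observations, weekly regional counts, boundary polygons,
a gridded pollution field) over a rectangle at Ireland-like coordinates,
and writes hidden answer files (true nearest station, true region, true
window means) so the whole pipeline can be scored for exact recovery.

## Worked example

```
geoweave generate-fixtures --out data --seed 1
geoweave run-all --fixtures data --out results
```

prints (stderr log):

```
stage=generate patients=20 stations=8 regions=6 days=90
stage=uplift triples=4034 duration=0.05s
stage=enrich triples=4190 duration=0.02s
stage=downlift rows=20 duration=0.03s
enriched_rows: 20
enriched_triples: 4190
provenance_violations: 0
uplift_triples: 4034
```

`results/enriched.csv` then holds one row per patient; the first row reads

```
patient=http://data.avert.ie/patient/P000, gender=Male,
date_of_birth=1979-11-19, diagnosis_date=2016-02-15,
nearest_station=.../Station%2005%20Automatic%20Weather%20Station%20(AWS),
nearest_station_km=164.97307490397657, region=.../region/LHO_05,
diagnosis_week_count=19, mean_temperature=2.506666666666667, ...
```

i.e. patient P000's nearest synthetic station is number 05 at ~165 km, the
patient sits in health region 05 where 19 cases were reported in the ISO
week of diagnosis, and mean temperature at that station over the 7 days
before diagnosis was 2.51 °C (missing observation days skipped). A
`geoweave validate --graph results/graph_enriched.nt` run exits 0: every
derived triple traces to a recorded activity.

Queries run from YAML specs, e.g. patients joined to their nearest
station's observations in a date window, excluding a comorbidity:

```yaml
patterns:
  - "?p rdf:type avert:Patient"
  - "?p avert:nearestStation ?s"
  - "?o avert:station ?s"
  - "?o avert:date ?d"
filters:
  - {kind: date_range, variable: d, start: 2016-01-10, end: 2016-01-16}
  - {kind: exclude_has_triple, variable: p, predicate: avert:comorbidity, object: '"asthma"'}
projection: [p, o]
```

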