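# Methods

## Data model

The integration substrate is an in-memory RDF graph restricted to the
subset the linkage task needs: subjects and predicates are absolute IRIs,
objects are IRIs or typed literals, there are no blank nodes (every
resource is minted an IRI from its source key) and no named graphs.
Literal equality — and hence graph set membership — is equality of the
(lexical form, datatype IRI) pair with no value-space canonicalization:
`"1.0"^^xsd:double` and `"1.00"^^xsd:double` are distinct terms. This
makes serialize/parse round-trips exact and diffs meaningful, at the cost
of treating numerically equal literals as different; the uplift layer
therefore never reformats numerics it copies. The persistence format is
N-Triples (one sorted line per triple, UTF-8), chosen as the simplest
line-oriented W3C format; everything that yields a sequence (matches,
bindings, serialization) is sorted so identical inputs give byte-identical
outputs.

## Uplift

Mappings are a declarative R2RML-style subset expressed in YAML: subject
IRI templates with `{column}` placeholders, constant predicates,
column-valued objects with optional datatype and transform. IRI template
values are percent-encoded per RFC 3986 with parentheses (sub-delims) kept
literal — a station label `"… (AWS)"` becomes `…%20(AWS)`. Two transforms
cover the source conventions: date normalization from a `dd-MM-yyyy`-style
pattern to the `xsd:date` lexical space, rejecting impossible calendar
dates; and codebook decoding (e.g. gender `0 → Female`, `1 → Male`) with a
configurable unmapped-code policy. A missing (empty) cell skips that one
triple, never the row: the source tables are sparse and one absent
observation must not erase a row's other facts. The triple-count identity
`|G| = Σ_rows (types + non-missing object maps)` holds by construction and
is property-tested.

Gridded (NetCDF-interface) fields are reduced to tables before uplift:
`subset_grid` keeps cells whose centre lies in a closed bounding box and
whose date lies in a closed range, one row per (time, lat, lon). Closed
intervals and centre-membership are the simplest contracts to state and
test; a bbox disjoint from the grid is an empty table, not an error. The
NetCDF interface uses xarray with the scipy backend; the in-memory
`GriddedField` is the tested surface.

## Spatial conventions

All coordinates are WGS84 with longitude-first (CRS84) axis order; a
`geo:wktLiteral` carrying an explicit different CRS is rejected rather
than reinterpreted. Distance is the haversine great-circle formula on the
IUGG mean-radius sphere R = 6371.0088 km. Nearest-station ties are broken
by lexicographically smallest station IRI — deterministic and auditable.
Containment is planar even-odd ray casting in (lon, lat) coordinates with
boundary points counted inside; at the county scale of the target
geography the spherical-vs-planar discrepancy is far below boundary-data
uncertainty, which is a documented limitation, not a parameter. Polygons
are single rings, validated non-degenerate and non-self-intersecting at
construction; multi-polygons and holes are out of scope. Region
assignment assumes one administrative level at a time and raises an
ambiguity error listing candidates if a point falls in two regions.

## Temporal conventions

Weekly surveillance counts are keyed by ISO-8601 week; the source systems
do not state their convention, so ISO is the default and US CDC
epidemiological weeks (Sunday start) are available as a stated
non-default. The exposure window anchored at diagnosis date *d* with
length *n* is the closed interval `[d − n, d − 1]` — strictly prior to
diagnosis, since the scientific question concerns antecedent conditions —
or `[d − n + 1, d]` when the diagnosis day is explicitly included; the
window always spans exactly *n* days.

## Provenance

Every derivation run (spatial links, weekly-count linkage, downlift) is a
`prov:Activity` with start/end `xsd:dateTime`, an associated agent IRI,
`prov:used` inputs and generated outputs: 4 core triples + |used| +
|generated|. Generated entities are reified at batch granularity — one
entity per run, linked to covered subjects via `prov:hadMember` and to the
predicates it materialized via a bespoke `materializesPredicate` property —
keeping provenance size linear in enriched resources while still letting
the validator flag a derived triple on a subject no batch covers.
Per-triple entities would be fully precise but would double the graph;
batch granularity is the deliberate trade-off, and its blind spot (a
hand-inserted triple re-using an already-covered subject+predicate pair)
is documented. Timestamps come from a logical clock (fixed epoch, one
second per activity) rather than the wall clock, because byte-identical
re-runs are a harder requirement than literal run times; the agent
defaults to the OS user name.

## Downlift

The analytic table is case-level: one row per patient ordered by IRI.
Attribute columns copy the stored lexical form bit-exactly (IRI strings
for resource objects). Window aggregates (mean, sum, min, max, count)
operate on the patient's nearest-station observations inside the exposure
window, in chronological order so floating-point sums are independent of
incidental graph ordering. Missing-value policy is `skip` (aggregate the
present values) or `strict` (any gap ⇒ NA); empty windows are NA except
`count`, which is 0. Computed aggregates print as shortest-repr decimals,
integral values without a trailing `.0`. NA is an empty CSV field by
default.

## Synthetic data

The generator emulates the study's dataset inventory at test scale:
default 20 patients, 8 stations, 6 regions tiling a −11…−5 °E, 51…55.5 °N
rectangle, 90 daily time steps, a 10×10 gridded pollution field, 5%
observation missingness, gender coded 0/1, and all dates printed
`dd-MM-yyyy` so normalization is always exercised. Station temperature is
a seasonal sinusoid plus Gaussian noise around a per-station offset;
weekly regional counts are sums of a hidden Poisson daily-incidence
series, making week-sum consistency checkable; patients are placed
strictly inside one region (10% cell margin) with diagnosis dates late
enough that the exposure window lies within the observed span. Answer
files (true nearest station by brute force, true region by construction,
true window means recomputed from the printed observation lexicals) are
written beside the inputs so enrichment can be scored for exact recovery;
the required recovery rate is 100%. The generator reproduces shapes,
granularities and encodings — not disease clustering, station-siting bias
or weather autocorrelation — so green tests demonstrate mechanical
correctness of the linkage, not epidemiological realism of any inference
drawn from real data.

## Numerical and scale choices

Fixture scale (tens of patients, thousands of triples) keeps every
algorithm at its simplest correct form: linear-scan spatial search,
hash-join pattern evaluation, full-graph validation scans. The acceptance
script runs three pipeline seeds, 20×(50 patient × 200 station)
nearest-neighbour comparisons, 1000 point/polygon oracle pairs, 200
query-oracle pairs and 500 counting-identity trials in a few seconds on
one CPU; these sizes were chosen as the smallest that exercise ties,
boundaries and missingness convincingly. Degenerate inputs fail loudly:
zero-area or self-intersecting polygons, empty station lists, duplicate
(region, week) count records, duplicate activity IRIs, invalid calendar
dates.

## Known limitations

Planar containment and single-ring polygons (no islands/holes); no OWL/RDFS
inference, SPARQL text parsing, or remote federation; weekly reconciliation
assumes the surveillance week convention is uniform across the dataset;
nearest-station exposure assignment ignores elevation and coastal effects —
it is a deliberate, fully-documented in-house linkage rule, favouring
transparent provenance over externally modelled (and possibly more
accurate) gridded estimates.
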