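# Methods

## Ontology model

The EWSSO is built programmatically from two declarative tables
(`src/ewsso/data/terms.yaml`, `axioms.yaml`): one row per class with label,
parent, textual definition and provenance, and one row per
subject–property–object axiom. The build enforces the construction rules a
curator would: unique IRIs and labels, every parent resolvable, an acyclic
taxonomy, and a non-empty genus–differentia style textual definition on
every newly created class. Upper-level classes (`process`, `planned
process`, `information content entity`, `measurement datum`) and the four
object properties (`is about`, `is_specified_output_of`,
`has_specified_input`, `has_specified_output`) are shallow MIREOT-style
stubs: they keep their canonical BFO/OBI/IAO PURLs and definitions but are
never fetched over the network, so builds are offline and deterministic.
New classes are minted under a configurable placeholder namespace
(`http://example.org/ewsso#`) pending any registry-assigned prefix.

Axioms are stored as plain records and emitted in OWL as existential
restrictions (`rdfs:subClassOf [ owl:onProperty P; owl:someValuesFrom O ]`)
on the subject class — a reasoner-friendly encoding for "the NEWS summation
process has specified input respiratory rate measurement datum". The class
definition texts describe the summation processes as consuming the vital
measurement data and the scoring processes as producing the per-parameter
datum scores, and that is exactly how the axioms are laid out: summation
processes carry the 7/6/3 `has_specified_input` axioms (these sets are what
`required_inputs` exposes and what drives retrieval), scoring processes
carry `has_specified_output` axioms to the datum-score classes, and each
summation process outputs its score class. The per-parameter datum-score
classes are placed under `measurement datum`: they are recorded point
values, i.e. information content, and this placement avoids importing any
further process class. Serialization round-trips (Turtle and RDF/XML) are
exact for the term/property/axiom sets and are tested in both formats.

## Synthetic vitals generator

The generator emulates a single-snapshot critical-care vitals table: one
row per patient, no timestamps, no physiological correlation between
columns. Numeric vitals are sampled from a normal distribution specified by
its median and IQR — σ recovered as IQR / (2 · Φ⁻¹(0.75)) — and truncated
to an extreme range by rejection (resampling out-of-range draws, capped at
10,000 attempts per value) rather than clipping, which would pile mass on
the bounds. Values are recorded at fixed precision: integers for RR, SpO₂,
SBP, HR and GCS; 0.1 for temperature and urine output. The default
parameters (e.g. RR median 18, IQR 16–20, range 4–45; temperature median
36.9 °C, IQR 36.5–37.3, range 33–42) are structural placeholders shaped
like an emergency-department cohort; the extreme ranges are chosen so every
band of every rubric is reachable. They live in
`src/ewsso/data/distributions.yaml` and carry no claim of fidelity to any
specific published cohort — anyone wanting cohort realism should substitute
measured values there.

Consciousness is generated once as an AVPU category (defaults A 0.85,
V 0.08, P 0.04, U 0.03) and GCS is *derived* from it via the published
correlation (A→15, V→12, P→8, U→3), never sampled independently, so the two
columns can never disagree. Supplemental oxygen is Bernoulli(0.2);
temperatures are re-expressed in °F for a seeded 50% of patients (rounded
to 0.1 °F); each non-identifier cell is independently blanked with
probability 0.05, with a temperature and its unit tag blanking together.
The distractor dataset appends age, sex, weight, diastolic pressure,
admission ward and pain score — disjoint by construction from every score's
required inputs. Missingness applies to all non-identifier columns alike.

Seeding uses one `numpy` `SeedSequence` spawned into per-column child
streams in fixed order, so adding a column never reshuffles existing ones
and a given (config, seed) pair reproduces the CSV byte-for-byte. What
passing tests show is therefore structural: marginal distributions match
their specs, invariants hold, and the pipeline behaves correctly on data of
this shape. They do not show anything about covariance, trajectories or
real-world missingness mechanisms, which the generator deliberately does
not model.

## Semantic store

Triplification mints `data:patient/<id>` and
`data:measurement/<id>/<Column>` nodes; each measurement is typed by the
EWSSO class its column maps to (`data/column_map.yaml`), holds its value as
a typed literal (integers as `xsd:integer`; fixed-precision decimals with
their lexical form preserved, so Turtle round-trips are exact) and its unit
as a plain literal. Distractor columns are triplified too, typed in a
separate non-score namespace: differentiation between necessary and
unnecessary features is then a query-time property driven by the ontology,
not an artifact of dropping columns at load time. Missing cells produce no
node at all.

Retrieval is SPARQL 1.1 against the in-memory graph. Score-scoped
retrieval restricts the measurement class to the summation process's
specified-input set via a `VALUES` clause placed *after* the graph pattern;
with the patient id pre-bound this keeps evaluation on the per-patient
index (placing `VALUES` first makes the engine enumerate all measurements
of those classes per query — two orders of magnitude slower at 1,000
patients). Queries are prepared once and reused. An unknown patient id
raises a lookup error, distinct from an empty result for an all-missing
row.

## Scoring

Rubrics are data (`data/rubrics/*.yaml`): per parameter either numeric
bands `[lower, upper, points]` (null = unbounded) or a category→points map.
Band boundaries are interpreted as closed intervals on the
recording-precision grid; values are rounded to that precision and compared
as scaled integers, so an edge such as 38.05 °C cannot fall between bands.
At load time every parameter is swept across its declared domain and must
hit exactly one band per grid point — a malformed chart fails fast, not at
scoring time. The shipped bands follow the standard published charts
(NEWS chart; a six-item MEWS chart with urine output in mL/kg/h; the
Sepsis-3 qSOFA criteria); because the primary sources publish them as
images, the YAML is the single place to reconcile against a local protocol.

Scoring applies conversions first — °F→°C by (t − 32) × 5/9, unrounded
until the scoring boundary; AVPU→GCS when a rubric requires GCS and only an
AVPU assessment is present — and attaches an audit record to the component
score. The minimum-data rule is strict: a score is computed iff every
required input is available, otherwise the result is `unavailable` with the
exact missing set; nothing is imputed. Extra measurements (distractors) are
ignored; duplicate measurements for one class are an error under the
single-snapshot model. In the pipeline flow, qSOFA's consciousness input
comes from the GCS column (ontology-driven retrieval returns only the three
qSOFA classes), so a blanked GCS makes qSOFA unavailable even when AVPU is
present — the AVPU fallback serves direct API callers who pass an AVPU
measurement.

Score definitions are a registry of rubric configs discovered at load;
adding a score is a YAML file plus, if needed, a conversion registration,
with no engine change.

## Validation harnesses

* **Feature differentiation** — for all 1,000 distractor-dataset patients ×
  3 scores, the scoped retrieval must contain no non-required class, every
  required class whose source cell is non-missing, and no surplus
  measurements (the count check is what catches a mis-tagged column that
  hides inside a required class). Reported as conforming / 3,000.
* **Temperature conversion** — for every Fahrenheit-recorded, scored
  (patient, score) pair: the audited conversion must equal the closed form
  within 1e-9, the applied-flag must be set, and re-scoring with the
  pre-converted Celsius value must leave the total unchanged; Celsius pairs
  fail (and count) only if a spurious conversion appears. An all-Celsius
  run is a flagged vacuous pass.
* **Chart oracle** — ten seeded patients are rescored by an independent
  straight-line if/else chart lookup that shares no band code with the
  engine and reads the CSV row directly (its own inline °F→°C and AVPU
  handling); statuses and totals must agree. The same oracle also backs an
  exhaustive per-parameter sweep in the test suite: every rubric parameter
  is swept over its full domain at recording precision with the other
  parameters held at zero-point values, in both temperature units.

Both self-test directions are exercised: a deliberately corrupted column
map drops the differentiation fraction below 1, and stripping the
conversion audits drops the temperature fraction below 1.

## Problem sizes and numerical choices

The shipped validation runs at the study's native scale — 1,000 patients
per dataset, 3,000 retrievals, k = 10 oracle patients — and completes in
well under a minute on one CPU; distributional-recovery checks use 100,000
draws per vital. Rounding is Python/numpy round-half-even throughout, used
identically by the engine, the generator and the oracles. Monte-Carlo
tolerances for the generator are ±0.5% of the range width on the median and
±1% on the IQR endpoints at n = 100,000; recording discreteness makes the
integer vitals land exactly on their configured quartiles, and the
truncation-induced shift for the one noticeably asymmetric spec (urine
output, truncated at 0) stays inside those tolerances.

## Known limitations

* Vitals are marginally realistic but jointly independent; no repeated
  measures, so nothing here validates trend-based alerting.
* The ontology ships no DL reasoning; taxonomy queries use the explicit
  parent links. The `validate_ontology` audit is structural, not a
  dashboard-compliance check.
* Default distribution parameters and the six-item MEWS urine-output bands
  are configuration defaults, not authoritative clinical values; both are
  isolated in YAML for exactly that reason.
* The SPARQL layer targets the in-memory engine; pointing the same queries
  at a remote SPARQL 1.1 endpoint is a store-contract swap but is not
  implemented here.
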