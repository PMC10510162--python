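# ewsso — early warning system scores ontology toolkit

Early warning scores (EWSs, "track and trigger" systems) aggregate vital-sign
measurements into a single number that flags clinical deterioration before it
becomes an adverse event. Because different hospitals run different scores on
different EHR systems, the same physiological data end up labelled in
incompatible ways, which blocks secondary analysis across providers. This
package addresses that with an ontology: the Early Warning System Scores
Ontology (EWSSO) formally models three widely used scores —

* **NEWS** (National Early Warning Score): seven inputs (respiratory rate,
  SpO₂, supplemental oxygen use, body temperature, systolic blood pressure,
  heart rate, AVPU), total 0–20;
* **six-item MEWS** (Modified Early Warning Score): six inputs including
  urine output, total 0–17;
* **qSOFA** (quick Sequential Organ Failure Assessment): three binary
  criteria (respiratory rate ≥ 22 /min, systolic BP ≤ 100 mmHg, GCS < 15),
  total 0–3.

Each score is modelled as an *information content entity* that is about
clinical deterioration and is the specified output of a *summation process*
(a planned process) whose `has_specified_input` axioms name exactly the
measurement-datum classes the score requires. The ontology comprises 29 new
classes plus 4 classes and 4 object properties reused as MIREOT-style stubs
from BFO, OBI and IAO.

Around the ontology the package provides the full validation pipeline:

1. **synthetic data** — two 1,000-patient single-snapshot vitals tables.
   Numeric vitals are drawn from a normal distribution parameterized by
   median and IQR (σ = IQR / (2 · Φ⁻¹(0.75)) = IQR / 1.3489795…) and
   truncated to an extreme range by rejection sampling; GCS is derived from
   AVPU (A→15, V→12, P→8, U→3); temperatures are recorded per patient in °F
   or °C; cells are blanked at a configurable missingness rate. The second
   table adds distractor clinical/demographic columns no score uses.
2. **semantic store** — the tables are triplified into an RDF graph, every
   measurement typed by its ontology class (distractors in a separate
   namespace), and retrieved per patient via SPARQL 1.1; retrieval for a
   score is restricted to the classes its summation process specifies.
3. **scoring** — rubric band tables (configuration, not code) map each
   converted input to points and sum them; a missing required input makes
   the score `unavailable` (nothing is imputed), and °F temperatures are
   converted with (t − 32) × 5/9 before banding, with an audit record.
4. **validation** — feature differentiation (retrievals contain exactly the
   score-relevant data), temperature-conversion correctness and unit
   invariance, and a seeded 10-patient comparison against an independent
   straight-line chart-lookup oracle.

## Worked example

```python
from ewsso import (build_ewsso, load_default_rubrics, load_config,
                   generate_vitals_dataset, table_to_triples, compute_all_scores)

model = build_ewsso()                      # 29 new + 4 imported classes
rubrics = load_default_rubrics(model)
cfg = load_config(); cfg.n_patients = 5
table = generate_vitals_dataset(cfg, seed=7)
pg = table_to_triples(table, model)
for pid in table["patient_id"]:
    res = compute_all_scores(pg, pid, model, rubrics)
    print(pid, {k: (v.total if v.status == "scored" else "unavailable")
                for k, v in res.items()})
```

prints

```
P0001 {'NEWS': 0, 'MEWS6': 1, 'qSOFA': 0}
P0002 {'NEWS': 6, 'MEWS6': 5, 'qSOFA': 2}
P0003 {'NEWS': 'unavailable', 'MEWS6': 'unavailable', 'qSOFA': 0}
P0004 {'NEWS': 7, 'MEWS6': 5, 'qSOFA': 2}
P0005 {'NEWS': 6, 'MEWS6': 4, 'qSOFA': 0}
```

Patient P0002, for instance, was generated with RR 22, HR 102, SBP 121,
97.5 °F (= 36.4 °C) and AVPU = V: NEWS = 2+0+0+0+0+1+3 = 6, and qSOFA = 2
because RR ≥ 22 and the AVPU-derived GCS of 12 is below 15. P0003's AVPU
cell is blank, so NEWS and MEWS6 are reported `unavailable` rather than
computed from partial data (qSOFA still scores: it uses GCS, which is
present).

The same stages are scriptable from a shell:

```bash
ewsso gen-data --n 1000 --seed 1 --out vitals.csv
ewsso build-ontology --out ewsso.ttl
ewsso triplify --data vitals.csv --out graph.ttl
ewsso score --graph graph.ttl --patient P0001
ewsso run-all --seed 1 --n 1000 --outdir out/   # everything + validation
```

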