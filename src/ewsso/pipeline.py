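"""End-to-end orchestration: generate, triplify, query, score, validate.

The validation stage reproduces the two headline checks of the ontology
evaluation — that ontology-driven retrieval differentiates score-relevant
from irrelevant features on every query, and that temperature unit
conversion is applied correctly for every Fahrenheit-recorded patient —
plus a seeded k-patient comparison of the scoring engine against an
independent straight-line chart-lookup oracle (implemented here with no
shared band code, mirroring a manual calculation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import synthetic_data as sd
from .errors import EwssoError
from .ews_scoring import (
    EWSResult,
    Rubric,
    STATUS_SCORED,
    STATUS_UNAVAILABLE,
    compute_all_scores,
    compute_score,
    load_default_rubrics,
    results_to_json,
)
from .ontology_model import (
    OntologyModel,
    build_ewsso,
    required_inputs,
    serialize_ontology,
    validate_ontology,
)
from .semantic_store import (
    ColumnMap,
    MeasurementDatum,
    PatientGraph,
    load_column_map,
    query_score_inputs,
    serialize_graph,
    table_to_triples,
)
from .synthetic_data import ID_COLUMN, TEMPERATURE_COLUMN, TEMPERATURE_UNIT_COLUMN

SCORES = ("NEWS", "MEWS6", "qSOFA")


# ---------------------------------------------------------------------------
# independent chart-lookup oracle (no shared code with the rubric engine)
# ---------------------------------------------------------------------------

def _oracle_temp_c(row) -> float | None:
    t, unit = row.get(TEMPERATURE_COLUMN), row.get(TEMPERATURE_UNIT_COLUMN)
    if t is None:
        return None
    if unit == "degF":
        return round((t - 32) * 5 / 9, 1)
    return t


def oracle_news(row: dict) -> tuple[str, int | None]:
    """Manual NEWS chart lookup from a dataset row."""
    t = _oracle_temp_c(row)
    needed = [row.get("respiratory_rate"), row.get("oxygen_saturation"),
              row.get("supplemental_oxygen"), t, row.get("systolic_blood_pressure"),
              row.get("heart_rate"), row.get("avpu")]
    if any(v is None for v in needed):
        return STATUS_UNAVAILABLE, None
    rr, spo2, o2, _, sbp, hr, avpu = needed
    total = 0
    total += 3 if rr <= 8 else 1 if rr <= 11 else 0 if rr <= 20 else 2 if rr <= 24 else 3
    total += 3 if spo2 <= 91 else 2 if spo2 <= 93 else 1 if spo2 <= 95 else 0
    total += 2 if o2 == "yes" else 0
    total += 3 if t <= 35.0 else 1 if t <= 36.0 else 0 if t <= 38.0 else 1 if t <= 39.0 else 2
    total += 3 if sbp <= 90 else 2 if sbp <= 100 else 1 if sbp <= 110 else 0 if sbp <= 219 else 3
    total += 3 if hr <= 40 else 1 if hr <= 50 else 0 if hr <= 90 else 1 if hr <= 110 else 2 if hr <= 130 else 3
    total += 0 if avpu == "A" else 3
    return STATUS_SCORED, total


def oracle_mews6(row: dict) -> tuple[str, int | None]:
    """Manual six-item MEWS chart lookup from a dataset row."""
    t = _oracle_temp_c(row)
    needed = [row.get("respiratory_rate"), row.get("heart_rate"),
              row.get("systolic_blood_pressure"), t, row.get("avpu"),
              row.get("urine_output")]
    if any(v is None for v in needed):
        return STATUS_UNAVAILABLE, None
    rr, hr, sbp, _, avpu, uo = needed
    total = 0
    total += 2 if rr <= 8 else 0 if rr <= 14 else 1 if rr <= 20 else 2 if rr <= 29 else 3
    total += 2 if hr <= 40 else 1 if hr <= 50 else 0 if hr <= 100 else 1 if hr <= 110 else 2 if hr <= 129 else 3
    total += 3 if sbp <= 70 else 2 if sbp <= 80 else 1 if sbp <= 100 else 0 if sbp <= 199 else 2
    total += 2 if t <= 34.9 else 0 if t <= 38.4 else 2
    total += {"A": 0, "V": 1, "P": 2, "U": 3}[avpu]
    total += 3 if uo == 0 else 2 if uo < 0.5 else 1 if uo < 1.0 else 0
    return STATUS_SCORED, total


def oracle_qsofa(row: dict) -> tuple[str, int | None]:
    """Manual qSOFA criteria check from a dataset row."""
    gcs, rr, sbp = row.get("gcs"), row.get("respiratory_rate"), row.get("systolic_blood_pressure")
    if gcs is None or rr is None or sbp is None:
        return STATUS_UNAVAILABLE, None
    total = (1 if rr >= 22 else 0) + (1 if sbp <= 100 else 0) + (1 if gcs < 15 else 0)
    return STATUS_SCORED, total


ORACLES = {"NEWS": oracle_news, "MEWS6": oracle_mews6, "qSOFA": oracle_qsofa}


# ---------------------------------------------------------------------------
# validation harnesses
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    differentiation_fraction: float
    differentiation_checks: int
    temperature_conversion_fraction: float
    temperature_checks: int
    oracle_agreement: tuple[int, int]
    failures: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        agree, k = self.oracle_agreement
        return (
            self.differentiation_fraction == 1.0
            and self.temperature_conversion_fraction == 1.0
            and agree == k
        )

    def as_dict(self) -> dict:
        return {
            "differentiation_fraction": self.differentiation_fraction,
            "differentiation_checks": self.differentiation_checks,
            "temperature_conversion_fraction": self.temperature_conversion_fraction,
            "temperature_checks": self.temperature_checks,
            "oracle_agreement": list(self.oracle_agreement),
            "passed": self.passed,
            "failures": self.failures,
            "notes": self.notes,
        }


def differentiation_check(
    pg: PatientGraph,
    model: OntologyModel,
    table,
    column_map: ColumnMap | None = None,
) -> tuple[float, list[str]]:
    """Fraction of (patient, score) retrievals that are exactly right: only
    score-required measurement classes returned, and every required class
    whose source cell is non-missing actually returned.

    Over a distractor-bearing graph this is the feature-differentiation
    surface: any distractor leaking into a retrieval, or any required datum
    dropped, fails that pair.
    """
    column_map = column_map or load_column_map()
    col_for_class = {
        model.term_by_label(label).iri: col for col, label in column_map.vitals.items()
    }
    failures: list[str] = []
    checks = 0
    required_by_score = {s: required_inputs(model, s) for s in SCORES}
    for _, row in table.iterrows():
        pid = str(row[ID_COLUMN])
        for score in SCORES:
            checks += 1
            required = required_by_score[score]
            data = query_score_inputs(pg, pid, required)
            got = {d.datum_class_iri for d in data}
            extra = got - required
            expected = {
                iri for iri in required if row.get(col_for_class[iri]) is not None
            }
            dropped = expected - got
            # a mis-tagged column shows up as two measurements under one
            # required class, so compare counts as well as class sets
            surplus = len(data) - len(expected)
            if extra or dropped or surplus:
                failures.append(
                    f"{pid}/{score}: extra={sorted(extra)} dropped={sorted(dropped)} "
                    f"surplus={surplus}"
                )
    fraction = 1.0 if checks == 0 else (checks - len(failures)) / checks
    return fraction, failures


def temperature_conversion_check(
    pg: PatientGraph,
    model: OntologyModel,
    rubrics: dict[str, Rubric],
    table,
    results: dict[str, dict[str, EWSResult]],
) -> tuple[float, int, list[str]]:
    """Audit every scored (patient, score) pair whose rubric uses body
    temperature: Fahrenheit sources must show a conversion equal to
    (t − 32) × 5/9 within 1e-9, Celsius sources no conversion, and the
    score total must be invariant to re-scoring with the pre-converted
    Celsius value.

    The denominator counts Fahrenheit-recorded (patient, score) pairs; a
    Celsius pair enters only if it shows a spurious conversion (which both
    fails and counts), so an all-Celsius dataset yields a vacuous pass."""
    temp_iri = model.term_by_label("body temperature measurement datum").iri
    failures: list[str] = []
    checks = 0
    for _, row in table.iterrows():
        t, unit = row.get(TEMPERATURE_COLUMN), row.get(TEMPERATURE_UNIT_COLUMN)
        if t is None:
            continue
        pid = str(row[ID_COLUMN])
        for score in ("NEWS", "MEWS6"):
            res = results.get(pid, {}).get(score)
            if res is None or res.status != STATUS_SCORED:
                continue
            comp = next(c for c in res.components if c.datum_class_iri == temp_iri)
            if unit == "degF":
                checks += 1
                expected = (t - 32) * 5 / 9
                audited = comp.conversion
                if (
                    audited is None
                    or not audited.conversion_applied
                    or abs(audited.converted_value - expected) > 1e-9
                ):
                    failures.append(f"{pid}/{score}: bad conversion audit")
                    continue
                # invariance: replace the degF reading with the converted
                # Celsius value and re-score
                req = required_inputs(model, score)
                data = [
                    d
                    for d in query_score_inputs(pg, pid, req)
                    if d.datum_class_iri != temp_iri
                ]
                data.append(
                    MeasurementDatum(
                        patient_iri=pg.patients[pid],
                        datum_class_iri=temp_iri,
                        value=round(expected, 1),
                        unit="degC",
                    )
                )
                redone = compute_score(rubrics[score], data)
                if redone.total != res.total:
                    failures.append(
                        f"{pid}/{score}: total changed {res.total} -> {redone.total}"
                    )
            else:
                if comp.conversion is not None and comp.conversion.conversion_applied:
                    checks += 1
                    failures.append(f"{pid}/{score}: spurious conversion on degC input")
    fraction = 1.0 if checks == 0 else (checks - len(failures)) / checks
    return fraction, checks, failures


def oracle_validation(
    pg: PatientGraph,
    table,
    model: OntologyModel,
    rubrics: dict[str, Rubric],
    k: int = 10,
    seed: int = 0,
) -> tuple[int, int, list[str]]:
    """Seeded selection of *k* patients, each recomputed by the independent
    chart oracle and compared to engine output (status and total for all
    three scores)."""
    ids = [str(v) for v in table[ID_COLUMN]]
    if k > len(ids):
        raise EwssoError(f"k={k} exceeds patient count {len(ids)}")
    rng = np.random.default_rng(seed)
    chosen = [ids[i] for i in rng.choice(len(ids), size=k, replace=False)]
    rows = {str(r[ID_COLUMN]): r.to_dict() for _, r in table.iterrows()}
    failures: list[str] = []
    agree = 0
    for pid in chosen:
        engine = compute_all_scores(pg, pid, model, rubrics)
        ok = True
        for score in SCORES:
            status, total = ORACLES[score](rows[pid])
            res = engine[score]
            if res.status != status or res.total != total:
                ok = False
                failures.append(
                    f"{pid}/{score}: engine={res.status}/{res.total} "
                    f"oracle={status}/{total}"
                )
        agree += ok
    return agree, k, failures


# ---------------------------------------------------------------------------
# orchestrated run
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    seed: int = 0
    n_patients: int = 1000
    missing_rate: float = 0.05
    fahrenheit_fraction: float = 0.5
    validation_k: int = 10
    outdir: Path | None = None
    distributions: str | Path | None = None  # override packaged spec table

    def dataset_config(self) -> sd.DatasetConfig:
        cfg = sd.load_config(self.distributions)
        cfg.n_patients = self.n_patients
        cfg.missing_rate = self.missing_rate
        cfg.fahrenheit_fraction = self.fahrenheit_fraction
        return cfg


@dataclass
class PipelineResult:
    model: OntologyModel
    vitals: object
    distractor: object
    vitals_graph: PatientGraph
    distractor_graph: PatientGraph
    scores: dict[str, dict[str, EWSResult]]
    report: ValidationReport
    artifacts: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full study: build the ontology, generate both datasets,
    triplify, score every patient, and produce the validation report.
    Identical config and seed reproduce every artifact byte for byte."""
    model = build_ewsso()
    onto_report = validate_ontology(model)
    if not onto_report.passed:
        raise EwssoError(f"ontology validation failed: {onto_report.as_dict()}")

    ds_cfg = config.dataset_config()
    vitals = sd.generate_vitals_dataset(ds_cfg, seed=config.seed)
    distractor = sd.generate_distractor_dataset(ds_cfg, seed=config.seed)

    column_map = load_column_map()
    vitals_pg = table_to_triples(vitals, model, column_map)
    distractor_pg = table_to_triples(distractor, model, column_map)

    rubrics = load_default_rubrics(model)
    scores: dict[str, dict[str, EWSResult]] = {}
    for pid in vitals[ID_COLUMN]:
        scores[str(pid)] = compute_all_scores(vitals_pg, str(pid), model, rubrics)

    diff_frac, diff_failures = differentiation_check(distractor_pg, model, distractor, column_map)
    temp_frac, temp_checks, temp_failures = temperature_conversion_check(
        vitals_pg, model, rubrics, vitals, scores
    )
    notes = []
    if temp_checks == 0:
        notes.append("no temperature checks ran (no scored patients with temperature)")
    if config.n_patients == 0:
        notes.append("no patients generated; validation is vacuous")
        agree, k, oracle_failures = 0, 0, []
    else:
        agree, k, oracle_failures = oracle_validation(
            vitals_pg, vitals, model, rubrics,
            k=min(config.validation_k, config.n_patients), seed=config.seed,
        )
    report = ValidationReport(
        differentiation_fraction=diff_frac,
        differentiation_checks=3 * len(distractor),
        temperature_conversion_fraction=temp_frac,
        temperature_checks=temp_checks,
        oracle_agreement=(agree, k),
        failures=diff_failures + temp_failures + oracle_failures,
        notes=notes,
    )

    result = PipelineResult(
        model=model,
        vitals=vitals,
        distractor=distractor,
        vitals_graph=vitals_pg,
        distractor_graph=distractor_pg,
        scores=scores,
        report=report,
    )
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        result.artifacts["vitals_csv"] = sd.write_dataset(vitals, out / "vitals.csv")
        result.artifacts["distractor_csv"] = sd.write_dataset(distractor, out / "distractor.csv")
        result.artifacts["ontology_ttl"] = serialize_ontology(model, "turtle", out / "ewsso.ttl")
        result.artifacts["ontology_owl"] = serialize_ontology(model, "owl-rdfxml", out / "ewsso.owl")
        result.artifacts["vitals_graph"] = serialize_graph(vitals_pg, out / "vitals.ttl")
        result.artifacts["distractor_graph"] = serialize_graph(distractor_pg, out / "distractor.ttl")
        (out / "scores.json").write_text(results_to_json(scores))
        result.artifacts["scores_json"] = out / "scores.json"
        (out / "validation.json").write_text(json.dumps(report.as_dict(), indent=2))
        result.artifacts["validation_json"] = out / "validation.json"
    return result
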