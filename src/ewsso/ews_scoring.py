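"""Rubric-driven calculation of NEWS, the six-item MEWS and qSOFA.

Each score is a *rubric*: an ordered list of parameters keyed by the
ontology's measurement-datum classes, each with either numeric point bands
or a category-to-points map.  Band tables are configuration, not code, and
are validated at load time: over the parameter's plausible domain, swept at
recording precision, every value must fall in exactly one band.  Boundaries
are compared on the scaled-integer grid, so an edge like 38.05 °C cannot be
ambiguous — values are rounded to the recording precision first.

Scoring follows the minimum-data rule: if any required input is absent the
result is UNAVAILABLE, carrying the set of missing datum classes; scores
are never computed from partial data and missing values are never imputed.
Unit conversions (Fahrenheit to Celsius, AVPU to GCS where a rubric wants
GCS and only AVPU exists) are applied before band lookup and recorded as
audit entries on the component scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from .errors import DataError, RubricCoverageError, ScoreLookupError, UnitError
from .ontology_model import OntologyModel, required_inputs
from .semantic_store import MeasurementDatum, PatientGraph, query_score_inputs
from .unit_conversion import ConvertedValue, avpu_to_gcs, convert

STATUS_SCORED = "scored"
STATUS_UNAVAILABLE = "unavailable"

#: Named category-scale conversions a rubric may reference in `derive_from`.
_CATEGORY_CONVERSIONS = {"avpu_to_gcs": avpu_to_gcs}


@dataclass(frozen=True)
class RubricBand:
    """A closed interval [lower, upper] on the recording grid, worth
    `points`; ``None`` bounds are unbounded."""

    lower: float | None
    upper: float | None
    points: int


@dataclass
class RubricParameter:
    datum_label: str
    datum_iri: str
    unit: str | None = None
    precision: int = 0
    domain: tuple[float, float] | None = None
    bands: list[RubricBand] = field(default_factory=list)
    categories: dict[str, int] | None = None
    # optional fallback: (source datum IRI, conversion callable name)
    derive_from_iri: str | None = None
    derive_conversion: str | None = None

    @property
    def scale(self) -> int:
        return 10 ** self.precision

    def max_points(self) -> int:
        if self.categories is not None:
            return max(self.categories.values())
        return max(b.points for b in self.bands)


@dataclass
class Rubric:
    score_name: str
    score_label: str
    parameters: list[RubricParameter]

    @property
    def max_total(self) -> int:
        return sum(p.max_points() for p in self.parameters)

    def required(self) -> set[str]:
        return {p.datum_iri for p in self.parameters}

    def parameter_for(self, datum_iri: str) -> RubricParameter:
        for p in self.parameters:
            if p.datum_iri == datum_iri:
                return p
        raise KeyError(datum_iri)


@dataclass
class ComponentScore:
    """Per-parameter outcome, keeping raw and converted values for audit."""

    datum_class_iri: str
    raw_value: float | str
    raw_unit: str | None
    converted_value: float | str
    converted_unit: str | None
    points: int
    conversion: ConvertedValue | None = None

    def as_dict(self) -> dict:
        return {
            "datum_class_iri": self.datum_class_iri,
            "raw_value": self.raw_value,
            "raw_unit": self.raw_unit,
            "converted_value": self.converted_value,
            "converted_unit": self.converted_unit,
            "points": self.points,
            "conversion": self.conversion.as_dict() if self.conversion else None,
        }


@dataclass
class EWSResult:
    score_name: str
    status: str
    total: int | None = None
    components: list[ComponentScore] = field(default_factory=list)
    missing_inputs: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "score": self.score_name,
            "status": self.status,
            "total": self.total,
            "components": [c.as_dict() for c in self.components],
            "missing_inputs": sorted(self.missing_inputs),
        }


# ---------------------------------------------------------------------------
# rubric loading and validation
# ---------------------------------------------------------------------------

def load_rubric(path: str | Path, model: OntologyModel) -> Rubric:
    """Load one rubric config, resolving datum labels against the ontology
    and validating band coverage/exclusivity over each parameter's domain."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    params: list[RubricParameter] = []
    for row in cfg["parameters"]:
        label = row["datum"]
        try:
            iri = model.term_by_label(label).iri
        except KeyError:
            raise RubricCoverageError(f"rubric parameter {label!r} not in ontology") from None
        derive_iri = derive_conv = None
        if row.get("derive_from"):
            derive_iri = model.term_by_label(row["derive_from"]["datum"]).iri
            derive_conv = row["derive_from"]["conversion"]
            if derive_conv not in _CATEGORY_CONVERSIONS:
                raise RubricCoverageError(f"unknown conversion {derive_conv!r}")
        param = RubricParameter(
            datum_label=label,
            datum_iri=iri,
            unit=row.get("unit"),
            precision=int(row.get("precision", 0)),
            domain=tuple(row["domain"]) if row.get("domain") else None,
            bands=[RubricBand(b[0], b[1], int(b[2])) for b in row.get("bands", [])],
            categories={str(k): int(v) for k, v in row["categories"].items()}
            if row.get("categories")
            else None,
            derive_from_iri=derive_iri,
            derive_conversion=derive_conv,
        )
        _validate_parameter(cfg["score"], param)
        params.append(param)
    return Rubric(score_name=cfg["score"], score_label=cfg["label"], parameters=params)


def _validate_parameter(score: str, param: RubricParameter) -> None:
    if param.categories is not None:
        if param.bands:
            raise RubricCoverageError(f"{score}/{param.datum_label}: both bands and categories")
        return
    if not param.bands or param.domain is None:
        raise RubricCoverageError(f"{score}/{param.datum_label}: bands and domain required")
    lo = round(param.domain[0] * param.scale)
    hi = round(param.domain[1] * param.scale)
    for v in range(lo, hi + 1):
        hits = [b for b in param.bands if _band_matches(b, v, param.scale)]
        if len(hits) != 1:
            raise RubricCoverageError(
                f"{score}/{param.datum_label}: value {v / param.scale} matches "
                f"{len(hits)} bands (expected exactly 1)"
            )


def _band_matches(band: RubricBand, scaled_value: int, scale: int) -> bool:
    lo = -10**9 if band.lower is None else round(band.lower * scale)
    hi = 10**9 if band.upper is None else round(band.upper * scale)
    return lo <= scaled_value <= hi


def load_default_rubrics(model: OntologyModel) -> dict[str, Rubric]:
    """The three packaged rubrics, keyed by short score name."""
    base = resources.files("ewsso.data") / "rubrics"
    rubrics = {}
    for name in ("news", "mews6", "qsofa"):
        r = load_rubric(Path(str(base / f"{name}.yaml")), model)
        rubrics[r.score_name] = r
    return rubrics


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def band_score(rubric: Rubric, datum_class_iri: str, value) -> ComponentScore:
    """Score one converted, precision-rounded value against its parameter.

    A numeric value outside every band signals a mis-specified rubric (the
    load-time validation should have caught it) and raises
    :class:`RubricCoverageError`.
    """
    param = rubric.parameter_for(datum_class_iri)
    if param.categories is not None:
        if value not in param.categories:
            raise RubricCoverageError(
                f"{rubric.score_name}/{param.datum_label}: unknown category {value!r}"
            )
        pts = param.categories[value]
        return ComponentScore(datum_class_iri, value, None, value, None, pts)
    scaled = round(float(value) * param.scale)
    for band in param.bands:
        if _band_matches(band, scaled, param.scale):
            return ComponentScore(
                datum_class_iri, value, param.unit, value, param.unit, band.points
            )
    raise RubricCoverageError(
        f"{rubric.score_name}/{param.datum_label}: value {value} outside all bands"
    )


def check_minimum_data(available: set[str], required: set[str]) -> tuple[bool, set[str]]:
    """Minimum-data rule: satisfied iff every required datum class is
    available; returns the missing set otherwise."""
    missing = set(required) - set(available)
    return (not missing, missing)


def compute_score(rubric: Rubric, measurements: Iterable[MeasurementDatum]) -> EWSResult:
    """Score one patient's semantically tagged measurements against a rubric.

    Applies unit conversions first (temperature to the rubric's Celsius
    scale; AVPU to GCS where the rubric declares that fallback), then bands
    each parameter and totals the points.  Measurements whose class the
    rubric does not mention are ignored.  If the minimum-data requirement
    is unmet the result is UNAVAILABLE and carries the missing classes.
    """
    by_class: dict[str, MeasurementDatum] = {}
    for m in measurements:
        if m.datum_class_iri in by_class:
            raise DataError(
                f"duplicate measurement for {m.datum_class_iri} (single-snapshot model)"
            )
        by_class[m.datum_class_iri] = m

    effective: set[str] = set()
    for p in rubric.parameters:
        if p.datum_iri in by_class:
            effective.add(p.datum_iri)
        elif p.derive_from_iri and p.derive_from_iri in by_class:
            effective.add(p.datum_iri)
    ok, missing = check_minimum_data(effective, rubric.required())
    if not ok:
        return EWSResult(rubric.score_name, STATUS_UNAVAILABLE, missing_inputs=missing)

    components: list[ComponentScore] = []
    for p in rubric.parameters:
        m = by_class.get(p.datum_iri)
        if m is None:  # derived fallback (e.g. GCS from AVPU)
            src = by_class[p.derive_from_iri]
            derived = _CATEGORY_CONVERSIONS[p.derive_conversion](src.value)
            comp = band_score(rubric, p.datum_iri, derived)
            comp.raw_value, comp.raw_unit = src.value, src.unit
            comp.conversion = ConvertedValue(src.value, "AVPU", derived, "GCS", True)
        elif p.categories is not None:
            comp = band_score(rubric, p.datum_iri, str(m.value))
        else:
            source_unit = m.unit if m.unit is not None else p.unit
            if source_unit == p.unit or p.unit is None:
                conv = None
                value = float(m.value)
            else:
                conv = convert(float(m.value), source_unit, p.unit)
                value = round(conv.converted_value, p.precision)
            comp = band_score(rubric, p.datum_iri, value)
            comp.raw_value, comp.raw_unit = float(m.value), source_unit
            comp.conversion = conv
        components.append(comp)

    total = sum(c.points for c in components)
    return EWSResult(rubric.score_name, STATUS_SCORED, total=total, components=components)


def compute_all_scores(
    pg: PatientGraph,
    patient_id: str,
    model: OntologyModel,
    rubrics: dict[str, Rubric] | None = None,
) -> dict[str, EWSResult]:
    """Query each score's ontology-specified inputs for one patient and
    compute every registered score independently; a patient may be scorable
    for one score and UNAVAILABLE for another."""
    rubrics = rubrics or load_default_rubrics(model)
    results: dict[str, EWSResult] = {}
    for name, rubric in rubrics.items():
        req = required_inputs(model, name)
        data = query_score_inputs(pg, patient_id, req)
        results[name] = compute_score(rubric, data)
    return results


def results_to_json(results: dict[str, dict[str, EWSResult]]) -> str:
    """Serialize a {patient_id: {score: result}} map as stable JSON."""
    payload = {
        pid: {name: res.as_dict() for name, res in scores.items()}
        for pid, scores in sorted(results.items())
    }
    return json.dumps(payload, indent=2, sort_keys=True)
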