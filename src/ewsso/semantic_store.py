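"""Ontology-informed RDF triplification and SPARQL retrieval.

A dataset table becomes a patient-centric RDF graph: one node per patient,
one measurement node per non-missing cell, each measurement typed by the
EWSSO measurement-datum class its column maps to.  Columns outside the
ontology (the distractor features) are still triplified, but typed in a
separate non-score namespace — differentiation between features necessary
and unnecessary for score calculation then happens at query time, driven by
the ontology's specified-input axioms.

Queries run as SPARQL 1.1 SELECTs against the in-memory rdflib graph (the
store contract is any SPARQL-1.1 engine; no server is required).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from rdflib import Graph, Literal, Namespace, RDF, URIRef, XSD
from rdflib.plugins.sparql import prepareQuery

from .errors import DataError, MappingError, PatientNotFoundError
from .ontology_model import OntologyModel, _slug
from .synthetic_data import ID_COLUMN, TEMPERATURE_UNIT_COLUMN

#: Vocabulary for the data graph (patients, measurement links, literals).
VOCAB = Namespace("http://example.org/ewsso/vocab#")
#: Base for minted patient/measurement individuals.
DATA = Namespace("http://example.org/ewsso/data/")
#: Namespace tagging measurements that are *not* EWSSO measurement data.
NONSCORE = Namespace("http://example.org/ewsso/nonscore#")


@dataclass(frozen=True)
class MeasurementDatum:
    """One semantically tagged observation retrieved from the graph."""

    patient_iri: str
    datum_class_iri: str
    value: float | int | str
    unit: str | None = None


@dataclass
class ColumnMap:
    """Dataset-column routing: score columns to EWSSO classes, unit columns
    to the column they annotate, everything else to the non-score namespace."""

    vitals: dict[str, str]          # column -> EWSSO class label
    unit_columns: dict[str, str]    # unit column -> measured column
    distractors: list[str] = field(default_factory=list)


def load_column_map(path: str | Path | None = None) -> ColumnMap:
    if path is None:
        path = Path(str(resources.files("ewsso.data") / "column_map.yaml"))
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return ColumnMap(
        vitals=dict(cfg.get("vitals") or {}),
        unit_columns=dict(cfg.get("unit_columns") or {}),
        distractors=list(cfg.get("distractors") or []),
    )


@dataclass
class PatientGraph:
    """An rdflib graph plus the patient-id index minted during load."""

    graph: Graph
    patients: dict[str, str] = field(default_factory=dict)  # patient_id -> IRI

    def __post_init__(self):
        if not self.patients:
            for p, pid in self.graph.subject_objects(VOCAB.patientId):
                self.patients[str(pid)] = str(p)

    def __len__(self) -> int:
        return len(self.graph)


def _literal(value) -> Literal:
    if isinstance(value, bool):
        return Literal(value)
    if isinstance(value, int):
        return Literal(value)
    if isinstance(value, float):
        # fixed-precision recorded values: keep the decimal lexical form so
        # Turtle round trips are exact
        return Literal(str(value), datatype=XSD.decimal)
    return Literal(str(value))


def table_to_triples(
    table: pd.DataFrame,
    model: OntologyModel,
    column_map: ColumnMap | None = None,
) -> PatientGraph:
    """Triplify a dataset: one patient node per row, one typed measurement
    node per non-missing mapped cell (missing cells produce nothing).

    Raises :class:`MappingError` if a mapped label is absent from the
    ontology and :class:`DataError` on duplicate patient ids.
    """
    column_map = column_map or load_column_map()
    class_iri: dict[str, URIRef] = {}
    for col, label in column_map.vitals.items():
        try:
            class_iri[col] = URIRef(model.term_by_label(label).iri)
        except KeyError:
            raise MappingError(f"column {col!r} mapped to unknown class {label!r}") from None
    for col in column_map.distractors:
        class_iri[col] = NONSCORE[_slug(col)]

    unit_of: dict[str, str] = {}  # measured column -> unit column
    for unit_col, measured in column_map.unit_columns.items():
        unit_of[measured] = unit_col

    g = Graph()
    g.bind("ewsso", Namespace(model.namespace))
    g.bind("vocab", VOCAB)
    g.bind("data", DATA)
    g.bind("nonscore", NONSCORE)

    patients: dict[str, str] = {}
    for _, row in table.iterrows():
        pid = str(row[ID_COLUMN])
        if pid in patients:
            raise DataError(f"duplicate patient id {pid!r}")
        p = DATA[f"patient/{pid}"]
        patients[pid] = str(p)
        g.add((p, RDF.type, VOCAB.Patient))
        g.add((p, VOCAB.patientId, Literal(pid)))
        for col, value in row.items():
            if col == ID_COLUMN or col in column_map.unit_columns or value is None:
                continue
            cls = class_iri.get(col)
            if cls is None:
                continue  # unmapped column, configured to be skipped
            m = DATA[f"measurement/{pid}/{_slug(col)}"]
            g.add((m, RDF.type, cls))
            g.add((m, VOCAB.hasValue, _literal(value)))
            g.add((p, VOCAB.hasMeasurement, m))
            unit_col = unit_of.get(col)
            if unit_col is not None and row[unit_col] is not None:
                g.add((m, VOCAB.hasUnit, Literal(str(row[unit_col]))))
    return PatientGraph(graph=g, patients=patients)


# ---------------------------------------------------------------------------
# SPARQL retrieval
# ---------------------------------------------------------------------------

_NS = {"vocab": VOCAB}


def _query_template(name: str) -> str:
    return (resources.files("ewsso.data") / "queries" / name).read_text()


_ALL_MEASUREMENTS = prepareQuery(_query_template("patient_measurements.rq"), initNs=_NS)

# per-required-set prepared queries, keyed by the frozenset of class IRIs
_SCOPED_CACHE: dict[frozenset, object] = {}


def _scoped_query(required: frozenset):
    q = _SCOPED_CACHE.get(required)
    if q is None:
        values = " ".join(f"<{iri}>" for iri in sorted(required))
        q = prepareQuery(
            _query_template("score_inputs.rq").replace("{values}", values), initNs=_NS
        )
        _SCOPED_CACHE[required] = q
    return q


def _to_datum(row) -> MeasurementDatum:
    value = row.value.toPython()
    if isinstance(value, decimal.Decimal):
        value = float(value)
    return MeasurementDatum(
        patient_iri=str(row.p),
        datum_class_iri=str(row.cls),
        value=value,
        unit=str(row.unit) if row.unit is not None else None,
    )


def query_patient_measurements(pg: PatientGraph, patient_id: str) -> list[MeasurementDatum]:
    """All measurement data attached to one patient, with class tags, values
    and units.  An unknown id raises :class:`PatientNotFoundError` (distinct
    from a patient whose row was entirely missing, which returns ``[]``)."""
    if patient_id not in pg.patients:
        raise PatientNotFoundError(patient_id)
    rows = pg.graph.query(_ALL_MEASUREMENTS, initBindings={"pid": Literal(patient_id)})
    return [_to_datum(r) for r in rows]


def query_score_inputs(
    pg: PatientGraph, patient_id: str, required: set[str]
) -> list[MeasurementDatum]:
    """Measurement data for one patient restricted to the classes a score's
    summation process specifies as inputs (never distractor-tagged data)."""
    if patient_id not in pg.patients:
        raise PatientNotFoundError(patient_id)
    if not required:
        return []
    rows = pg.graph.query(
        _scoped_query(frozenset(required)), initBindings={"pid": Literal(patient_id)}
    )
    return [_to_datum(r) for r in rows]


# ---------------------------------------------------------------------------
# Turtle persistence
# ---------------------------------------------------------------------------

def serialize_graph(pg: PatientGraph, path: str | Path) -> Path:
    path = Path(path)
    pg.graph.serialize(destination=str(path), format="turtle")
    return path


def load_graph(path: str | Path) -> PatientGraph:
    g = Graph()
    g.parse(str(path), format="turtle")
    return PatientGraph(graph=g)
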