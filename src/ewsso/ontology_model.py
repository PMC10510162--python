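"""Programmatic construction of the early warning system scores ontology.

The ontology (EWSSO) models three track-and-trigger scores — the National
Early Warning Score (NEWS), the six-item Modified Early Warning Score and
the quick Sequential Organ Failure Assessment (qSOFA) — as information
content entities about clinical deterioration.  Each score is the specified
output of a *summation process* (a planned process) whose specified inputs
are the vital-function measurement datum classes the score requires, while
a companion *scoring process* outputs the per-parameter measurement datum
score classes.  Upper-level classes (process, planned process, information
content entity, measurement datum) and the four object properties are
MIREOT-style stubs keeping their BFO/OBI/IAO source IRIs, so builds are
offline and deterministic.

Term and axiom content is declarative configuration (YAML), not code: adding
a new score is a config change only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef

from .errors import ConfigurationError, ScoreLookupError

DEFAULT_NAMESPACE = "http://example.org/ewsso#"

#: IAO annotation property for textual definitions.
IAO_DEFINITION = URIRef("http://purl.obolibrary.org/obo/IAO_0000115")

# Annotation vocabulary for provenance bookkeeping on serialization.
EWSSO_META = Namespace("http://example.org/ewsso/meta#")

#: Canonical score labels and the aliases accepted by :func:`required_inputs`.
SCORE_ALIASES: dict[str, str] = {
    "news": "national early warning score",
    "national early warning score": "national early warning score",
    "mews6": "six-item modified early warning score",
    "six-item mews": "six-item modified early warning score",
    "six-item modified early warning score": "six-item modified early warning score",
    "qsofa": "quick sequential organ failure assessment",
    "quick sequential organ failure assessment": "quick sequential organ failure assessment",
}

# Labels of the summation process class for each canonical score label.
_SUMMATION_LABEL = {
    "national early warning score": "national early warning score summation process",
    "six-item modified early warning score": "six-item modified early warning score summation process",
    "quick sequential organ failure assessment": "quick sequential organ failure assessment score summation process",
}


def _slug(label: str) -> str:
    """CamelCase IRI fragment from a class label."""
    words = re.sub(r"[^A-Za-z0-9 ]", " ", label).split()
    return "".join(w if w.isupper() else w.capitalize() for w in words)


@dataclass(frozen=True)
class OntologyTerm:
    """A class in the ontology, newly created or imported as a stub."""

    iri: str
    label: str
    textual_definition: str
    parent_iri: str | None
    provenance: str  # "new" | "imported"
    source_ontology: str | None = None


@dataclass(frozen=True)
class ObjectPropertyTerm:
    """An object property reused from an OBO Foundry ontology."""

    iri: str
    label: str
    definition: str
    source_ontology: str


@dataclass(frozen=True)
class InputAxiom:
    """A subject–property–object record emitted as an OWL existential
    restriction (someValuesFrom) on the subject class."""

    subject_iri: str
    property_iri: str
    object_iri: str


@dataclass
class OntologyModel:
    """In-memory EWSSO: terms, object properties and process axioms."""

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    properties: dict[str, ObjectPropertyTerm] = field(default_factory=dict)
    axioms: set[InputAxiom] = field(default_factory=set)
    namespace: str = DEFAULT_NAMESPACE

    # -- lookup helpers ----------------------------------------------------
    def term_by_label(self, label: str) -> OntologyTerm:
        for t in self.terms.values():
            if t.label == label:
                return t
        raise KeyError(label)

    def property_by_label(self, label: str) -> ObjectPropertyTerm:
        for p in self.properties.values():
            if p.label == label:
                return p
        raise KeyError(label)

    def new_terms(self) -> list[OntologyTerm]:
        return [t for t in self.terms.values() if t.provenance == "new"]

    def imported_terms(self) -> list[OntologyTerm]:
        return [t for t in self.terms.values() if t.provenance == "imported"]

    def is_descendant(self, iri: str, ancestor_iri: str) -> bool:
        """True if *iri* equals or sits below *ancestor_iri* in the taxonomy."""
        seen: set[str] = set()
        cur: str | None = iri
        while cur is not None and cur not in seen:
            if cur == ancestor_iri:
                return True
            seen.add(cur)
            term = self.terms.get(cur)
            cur = term.parent_iri if term else None
        return False

    def key_sets(self):
        """Hashable content view used for round-trip equality checks."""
        return (
            frozenset(self.terms.values()),
            frozenset(self.properties.values()),
            frozenset(self.axioms),
        )


# ---------------------------------------------------------------------------
# building from config
# ---------------------------------------------------------------------------

def _default_config_path(name: str) -> Path:
    return Path(str(resources.files("ewsso.data") / name))


def build_ewsso(
    term_table: str | Path | None = None,
    axiom_table: str | Path | None = None,
    namespace: str | None = None,
) -> OntologyModel:
    """Build the ontology from declarative term and axiom tables.

    Parameters default to the packaged configuration, which yields the full
    EWSSO: 29 new classes, 4 imported classes, 4 object properties.

    Raises
    ------
    ConfigurationError
        On duplicate IRIs/labels, a parent that does not exist, or an axiom
        referencing an unknown class or property.
    """
    term_path = Path(term_table) if term_table else _default_config_path("terms.yaml")
    axiom_path = Path(axiom_table) if axiom_table else _default_config_path("axioms.yaml")

    with open(term_path) as fh:
        term_cfg = yaml.safe_load(fh) or {}
    with open(axiom_path) as fh:
        axiom_cfg = yaml.safe_load(fh) or {}

    ns = namespace or term_cfg.get("namespace") or DEFAULT_NAMESPACE
    model = OntologyModel(namespace=ns)

    label_to_iri: dict[str, str] = {}
    for row in term_cfg.get("classes") or []:
        label = row["label"]
        provenance = row.get("provenance", "new")
        iri = row.get("iri") or ns + _slug(label)
        definition = (row.get("definition") or "").strip()
        if provenance == "new" and not definition:
            raise ConfigurationError(f"new class {label!r} lacks a textual definition")
        if iri in model.terms:
            raise ConfigurationError(f"duplicate IRI {iri}")
        if label in label_to_iri:
            raise ConfigurationError(f"duplicate label {label!r}")
        model.terms[iri] = OntologyTerm(
            iri=iri,
            label=label,
            textual_definition=definition,
            parent_iri=row.get("parent"),  # patched to an IRI below
            provenance=provenance,
            source_ontology=row.get("source_ontology"),
        )
        label_to_iri[label] = iri

    # resolve parent labels to IRIs once every class is known
    for iri, term in list(model.terms.items()):
        parent_label = term.parent_iri
        if parent_label is None:
            continue
        if parent_label not in label_to_iri:
            raise ConfigurationError(
                f"class {term.label!r} references unknown parent {parent_label!r}"
            )
        model.terms[iri] = OntologyTerm(
            iri=term.iri,
            label=term.label,
            textual_definition=term.textual_definition,
            parent_iri=label_to_iri[parent_label],
            provenance=term.provenance,
            source_ontology=term.source_ontology,
        )
    _check_acyclic(model)

    for row in term_cfg.get("object_properties") or []:
        iri = row.get("iri") or ns + _slug(row["label"])
        if iri in model.properties:
            raise ConfigurationError(f"duplicate property IRI {iri}")
        model.properties[iri] = ObjectPropertyTerm(
            iri=iri,
            label=row["label"],
            definition=(row.get("definition") or "").strip(),
            source_ontology=row.get("source_ontology", ""),
        )
    prop_by_label = {p.label: p.iri for p in model.properties.values()}

    for row in axiom_cfg.get("axioms") or []:
        for key in ("subject", "object"):
            if row[key] not in label_to_iri:
                raise ConfigurationError(f"axiom references unknown class {row[key]!r}")
        if row["property"] not in prop_by_label:
            raise ConfigurationError(f"axiom references unknown property {row['property']!r}")
        model.axioms.add(
            InputAxiom(
                subject_iri=label_to_iri[row["subject"]],
                property_iri=prop_by_label[row["property"]],
                object_iri=label_to_iri[row["object"]],
            )
        )
    return model


def _check_acyclic(model: OntologyModel) -> None:
    for iri in model.terms:
        seen: set[str] = set()
        cur: str | None = iri
        while cur is not None:
            if cur in seen:
                raise ConfigurationError(f"parent cycle involving {iri}")
            seen.add(cur)
            term = model.terms.get(cur)
            cur = term.parent_iri if term else None


# ---------------------------------------------------------------------------
# score input sets
# ---------------------------------------------------------------------------

def required_inputs(model: OntologyModel, score_label: str) -> set[str]:
    """IRIs of the measurement-datum classes a score's summation process
    declares as specified inputs (7 for NEWS, 6 for the six-item MEWS,
    3 for qSOFA).

    ``score_label`` accepts the full class label or the common abbreviation
    (NEWS / six-item MEWS / qSOFA), case-insensitively.
    """
    canonical = SCORE_ALIASES.get(score_label.strip().lower())
    if canonical is None:
        raise ScoreLookupError(f"unknown score label {score_label!r}")
    summation = model.term_by_label(_SUMMATION_LABEL[canonical])
    has_input = model.property_by_label("has_specified_input").iri
    md = model.term_by_label("measurement datum").iri
    return {
        ax.object_iri
        for ax in model.axioms
        if ax.subject_iri == summation.iri
        and ax.property_iri == has_input
        and model.is_descendant(ax.object_iri, md)
    }


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""
    offenders: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    new_class_count: int
    imported_class_count: int
    property_count: int
    checks: list[ValidationCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def as_dict(self) -> dict:
        return {
            "new_class_count": self.new_class_count,
            "imported_class_count": self.imported_class_count,
            "property_count": self.property_count,
            "passed": self.passed,
            "checks": [
                {"name": c.name, "passed": c.passed, "detail": c.detail, "offenders": c.offenders}
                for c in self.checks
            ],
        }


EXPECTED_NEW = 29
EXPECTED_IMPORTED = 4
EXPECTED_PROPERTIES = 4
EXPECTED_INPUT_COUNTS = {
    "national early warning score": 7,
    "six-item modified early warning score": 6,
    "quick sequential organ failure assessment": 3,
}


def validate_ontology(model: OntologyModel) -> ValidationReport:
    """Report-only consistency audit: class/property counts, definition
    coverage of new classes, taxonomy acyclicity and placement, and the
    per-score specified-input cardinalities."""
    checks: list[ValidationCheck] = []
    new = model.new_terms()
    imported = model.imported_terms()

    checks.append(
        ValidationCheck(
            "class_counts",
            len(new) == EXPECTED_NEW and len(imported) == EXPECTED_IMPORTED,
            f"{len(new)} new, {len(imported)} imported",
        )
    )
    checks.append(
        ValidationCheck(
            "property_count",
            len(model.properties) == EXPECTED_PROPERTIES,
            str(len(model.properties)),
        )
    )

    undefined = [t.label for t in new if not t.textual_definition.strip()]
    checks.append(
        ValidationCheck(
            "definition_coverage",
            not undefined,
            f"{len(new) - len(undefined)}/{len(new)} new classes defined",
            undefined,
        )
    )

    try:
        _check_acyclic(model)
        checks.append(ValidationCheck("acyclic_taxonomy", True))
    except ConfigurationError as exc:
        checks.append(ValidationCheck("acyclic_taxonomy", False, str(exc)))

    dangling = [
        ax
        for ax in model.axioms
        if ax.subject_iri not in model.terms or ax.object_iri not in model.terms
    ]
    checks.append(
        ValidationCheck(
            "axiom_references_resolve",
            not dangling,
            offenders=[f"{a.subject_iri} -> {a.object_iri}" for a in dangling],
        )
    )

    for score, expected in EXPECTED_INPUT_COUNTS.items():
        try:
            got = len(required_inputs(model, score))
            ok, detail = got == expected, f"{got} != {expected}" if got != expected else str(got)
        except (KeyError, ScoreLookupError) as exc:
            ok, detail = False, f"lookup failed: {exc}"
        checks.append(ValidationCheck(f"input_cardinality[{score}]", ok, detail))

    # taxonomy placement of the three modelled layers
    try:
        md = model.term_by_label("measurement datum").iri
        pp = model.term_by_label("planned process").iri
        ice = model.term_by_label("information content entity").iri
        ews = model.term_by_label("early warning score").iri
        misplaced = []
        for t in model.new_terms():
            if t.label.endswith("measurement datum") or t.label.endswith("measurement datum score"):
                if not model.is_descendant(t.iri, md):
                    misplaced.append(t.label)
            elif t.label.endswith("process") and t.label != "clinical deterioration":
                if not model.is_descendant(t.iri, pp):
                    misplaced.append(t.label)
            elif t.label.endswith("score") or t.label == "quick sequential organ failure assessment":
                if not (model.is_descendant(t.iri, ews) and model.is_descendant(t.iri, ice)):
                    misplaced.append(t.label)
        checks.append(ValidationCheck("taxonomy_placement", not misplaced, offenders=misplaced))
    except KeyError:
        pass  # partial models: placement check is inapplicable

    return ValidationReport(len(new), len(imported), len(model.properties), checks)


# ---------------------------------------------------------------------------
# serialization (OWL/RDF-XML and Turtle) and re-parsing
# ---------------------------------------------------------------------------

_FORMATS = {"owl-rdfxml": "pretty-xml", "turtle": "turtle", "ttl": "turtle", "owl": "pretty-xml"}


def to_graph(model: OntologyModel) -> Graph:
    """Render the model as an rdflib graph (OWL 2, restriction-style axioms)."""
    g = Graph()
    ns = Namespace(model.namespace)
    g.bind("ewsso", ns)
    g.bind("owl", OWL)
    g.bind("obo", "http://purl.obolibrary.org/obo/")
    g.bind("ewssometa", EWSSO_META)

    onto = URIRef(model.namespace.rstrip("#/"))
    g.add((onto, RDF.type, OWL.Ontology))

    for term in model.terms.values():
        s = URIRef(term.iri)
        g.add((s, RDF.type, OWL.Class))
        g.add((s, RDFS.label, Literal(term.label)))
        if term.textual_definition:
            g.add((s, IAO_DEFINITION, Literal(term.textual_definition)))
        if term.parent_iri:
            g.add((s, RDFS.subClassOf, URIRef(term.parent_iri)))
        g.add((s, EWSSO_META.provenance, Literal(term.provenance)))
        if term.source_ontology:
            g.add((s, EWSSO_META.sourceOntology, Literal(term.source_ontology)))

    for prop in model.properties.values():
        p = URIRef(prop.iri)
        g.add((p, RDF.type, OWL.ObjectProperty))
        g.add((p, RDFS.label, Literal(prop.label)))
        if prop.definition:
            g.add((p, IAO_DEFINITION, Literal(prop.definition)))
        if prop.source_ontology:
            g.add((p, EWSSO_META.sourceOntology, Literal(prop.source_ontology)))

    for ax in sorted(model.axioms, key=lambda a: (a.subject_iri, a.property_iri, a.object_iri)):
        restriction = BNode()
        g.add((restriction, RDF.type, OWL.Restriction))
        g.add((restriction, OWL.onProperty, URIRef(ax.property_iri)))
        g.add((restriction, OWL.someValuesFrom, URIRef(ax.object_iri)))
        g.add((URIRef(ax.subject_iri), RDFS.subClassOf, restriction))
    return g


def serialize_ontology(model: OntologyModel, fmt: str, path: str | Path) -> Path:
    """Write the ontology to *path* as ``owl-rdfxml`` or ``turtle``."""
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(_FORMATS)}")
    path = Path(path)
    to_graph(model).serialize(destination=str(path), format=_FORMATS[fmt])
    return path


def parse_ontology(path: str | Path, fmt: str | None = None) -> OntologyModel:
    """Re-read a serialized ontology into an :class:`OntologyModel`.

    Inverse of :func:`serialize_ontology` for the term/property/axiom sets.
    """
    g = Graph()
    rdf_format = _FORMATS.get(fmt, fmt) if fmt else None
    g.parse(str(path), format=rdf_format)

    model = OntologyModel()
    for onto in g.subjects(RDF.type, OWL.Ontology):
        base = str(onto)
        model.namespace = base if base.endswith(("#", "/")) else base + "#"

    for s in g.subjects(RDF.type, OWL.Class):
        if isinstance(s, BNode):
            continue
        label = g.value(s, RDFS.label)
        parent = None
        for o in g.objects(s, RDFS.subClassOf):
            if isinstance(o, URIRef):
                parent = str(o)
        definition = g.value(s, IAO_DEFINITION)
        source = g.value(s, EWSSO_META.sourceOntology)
        provenance = g.value(s, EWSSO_META.provenance)
        model.terms[str(s)] = OntologyTerm(
            iri=str(s),
            label=str(label) if label else "",
            textual_definition=str(definition) if definition else "",
            parent_iri=parent,
            provenance=str(provenance) if provenance else "new",
            source_ontology=str(source) if source else None,
        )

    for p in g.subjects(RDF.type, OWL.ObjectProperty):
        label = g.value(p, RDFS.label)
        definition = g.value(p, IAO_DEFINITION)
        source = g.value(p, EWSSO_META.sourceOntology)
        model.properties[str(p)] = ObjectPropertyTerm(
            iri=str(p),
            label=str(label) if label else "",
            definition=str(definition) if definition else "",
            source_ontology=str(source) if source else "",
        )

    for s, _, restriction in g.triples((None, RDFS.subClassOf, None)):
        if not isinstance(restriction, BNode):
            continue
        prop = g.value(restriction, OWL.onProperty)
        obj = g.value(restriction, OWL.someValuesFrom)
        if prop is not None and obj is not None:
            model.axioms.add(InputAxiom(str(s), str(prop), str(obj)))
    return model
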