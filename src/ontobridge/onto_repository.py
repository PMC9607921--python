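"""Ontology-based clinical repository.

Models the repository side of the pipeline as an OWL/RDF graph (rdflib):

* a fixed EN/ISO 13606 layer — ``ENTRY`` and ``ELEMENT`` classes plus the
  ``rc_id`` datatype property every entry instance carries;
* one concept class per archetype (e.g. ``Secondary_effect``), a subclass
  of ``ENTRY``, with one property per archetype element;
* a SNOMED CT metaclass: every bound concept (each finding and severity in
  the mapping config) is a class typed as an instance of that metaclass,
  annotated with its ``concept_id`` and ``code_uri``.  This expresses the
  terminology binding with plain ``rdf:type`` links, avoiding OWL-Full
  reasoning machinery.

Ingestion turns each extract entry into one instance of its concept class,
assigns a monotonically increasing ``rc_id``, and resolves the pseudonymous
app subject to the study-side identifier through the patient link table.
Ingestion is idempotent on ``extract_id``: re-sending an extract is a no-op
returning the original insertion results, so unattended daily re-sends are
harmless.  Reporting counts extracts and distinct patients per archetype
with half-up one-decimal percentages.
"""

from __future__ import annotations

import datetime as _dt
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict
from rdflib import RDF, RDFS, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, XSD

from .archetypes import EntryArchetype, ValidationReport, validate_extract
from .conversion import PatientLink
from .reference_model import (
    CodedValue,
    DateValue,
    ElementNode,
    EntryNode,
    ExtractDocument,
    QuantityValue,
    TextValue,
    canonicalize,
)
from .terminology import MappingConfig

__all__ = [
    "ONTO",
    "INST",
    "RepositoryError",
    "LinkageError",
    "IngestValidationError",
    "InsertionResult",
    "ArchetypeStats",
    "RepositoryReport",
    "OntologyRepository",
    "build_base_ontology",
    "pct",
]

ONTO = Namespace("https://ontobridge.org/onto#")
INST = Namespace("https://ontobridge.org/instance/")


class RepositoryError(RuntimeError):
    pass


class LinkageError(RepositoryError):
    """Extract subject has no entry in the patient link table."""


class IngestValidationError(RepositoryError):
    """Extract failed archetype validation; nothing was inserted."""

    def __init__(self, report: ValidationReport):
        self.report = report
        msgs = "; ".join(f"{i.path}: {i.message}" for i in report.errors)
        super().__init__(f"extract rejected by validation: {msgs}")


class InsertionResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    rc_id: int
    iri: str


def pct(numerator: int, denominator: int) -> float:
    """Percentage 100·n/d, rounded half-up to one decimal; 0.0 when the
    denominator is 0.  Negative inputs are errors."""
    if numerator < 0 or denominator < 0:
        raise ValueError("pct requires non-negative counts")
    if denominator == 0:
        return 0.0
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _class_iri(concept: str) -> URIRef:
    return ONTO[concept.replace(" ", "_")]


def _binding_class_iri(display: str) -> URIRef:
    safe = "".join(c if c.isalnum() else "_" for c in display).strip("_")
    return ONTO[safe or "Unnamed_concept"]


def build_base_ontology(
    registry: Mapping[str, EntryArchetype], mapping: MappingConfig
) -> Graph:
    """Build the knowledge-level graph: the 13606 layer, one ENTRY subclass
    per archetype with its element properties, and one SNOMED CT-bound
    class per mapping binding."""
    g = Graph()
    g.bind("onto", ONTO)
    g.bind("owl", OWL)

    # EN/ISO 13606 layer
    for cls in (ONTO.ENTRY, ONTO.ELEMENT):
        g.add((cls, RDF.type, OWL.Class))
    g.add((ONTO.ENTRY, RDFS.label, Literal("EN/ISO 13606 ENTRY")))
    g.add((ONTO.ELEMENT, RDFS.label, Literal("EN/ISO 13606 ELEMENT")))
    g.add((ONTO.rc_id, RDF.type, OWL.DatatypeProperty))
    g.add((ONTO.rc_id, RDFS.domain, ONTO.ENTRY))
    g.add((ONTO.SnomedCTConcept, RDF.type, OWL.Class))
    g.add(
        (ONTO.SnomedCTConcept, RDFS.label, Literal("SNOMED CT concept (metaclass)"))
    )
    for prop in (ONTO.concept_id, ONTO.code_uri):
        g.add((prop, RDF.type, OWL.AnnotationProperty))
    for prop in (ONTO.subject_id, ONTO.app_subject_id, ONTO.from_extract):
        g.add((prop, RDF.type, OWL.DatatypeProperty))

    # one concept class per archetype, one property per element
    for arch in registry.values():
        cls = _class_iri(arch.concept)
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, ONTO.ENTRY))
        g.add((cls, RDFS.label, Literal(arch.concept)))
        g.add((cls, ONTO.archetype_id, Literal(arch.archetype_id)))
        for c in arch.constraints:
            prop = ONTO[c.name]
            kind = OWL.ObjectProperty if c.value_kind == "coded" else OWL.DatatypeProperty
            g.add((prop, RDF.type, kind))
            g.add((prop, RDFS.domain, cls))

    # SNOMED CT metaclass instances for every binding
    for section in ("findings", "severities"):
        for b in mapping.section(section):  # type: ignore[arg-type]
            cls = _binding_class_iri(b.display)
            g.add((cls, RDF.type, OWL.Class))
            g.add((cls, RDF.type, ONTO.SnomedCTConcept))
            g.add((cls, RDFS.label, Literal(b.display)))
            g.add((cls, ONTO.concept_id, Literal(b.concept_id)))
            g.add((cls, ONTO.code_uri, URIRef(b.code_uri)))
    return g


class ArchetypeStats(BaseModel):
    model_config = ConfigDict(frozen=True)

    archetype_id: str
    n_extracts: int
    pct_extracts: float
    n_patients: int
    pct_patients: float


class RepositoryReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    total_extracts: int
    total_users: int
    per_archetype: tuple[ArchetypeStats, ...]

    def to_dict(self) -> dict:
        return {
            "total_extracts": self.total_extracts,
            "total_users": self.total_users,
            "archetypes": {
                s.archetype_id: {
                    "extracts": s.n_extracts,
                    "pct_extracts": s.pct_extracts,
                    "patients": s.n_patients,
                    "pct_patients": s.pct_patients,
                }
                for s in self.per_archetype
            },
        }

    def format_table(self) -> str:
        lines = [
            "EHR archetype    Extracts (N={}), n (%)    Patients (N={}), n (%)".format(
                self.total_extracts, self.total_users
            )
        ]
        for s in self.per_archetype:
            lines.append(
                f"{s.archetype_id:<16} {s.n_extracts} ({s.pct_extracts})"
                f"{'':<12} {s.n_patients} ({s.pct_patients})"
            )
        return "\n".join(lines)


class OntologyRepository:
    """The repository: knowledge graph + instance data + ingestion state."""

    def __init__(
        self,
        registry: Mapping[str, EntryArchetype],
        mapping: MappingConfig,
        graph: Optional[Graph] = None,
    ):
        self.registry = dict(registry)
        self.mapping = mapping
        self.graph = graph if graph is not None else build_base_ontology(registry, mapping)
        self._next_rc = 1 + max(
            (int(o) for o in self.graph.objects(None, ONTO.rc_id)), default=0
        )
        self._seen: dict[str, list[InsertionResult]] = {}
        for s, _, o in self.graph.triples((None, ONTO.from_extract, None)):
            rc = self.graph.value(s, ONTO.rc_id)
            self._seen.setdefault(str(o), []).append(
                InsertionResult(rc_id=int(rc), iri=str(s))
            )
        self._concept_by_id = {
            b.concept_id: b
            for sec in ("findings", "severities")
            for b in mapping.section(sec)  # type: ignore[arg-type]
        }

    # -- ingestion -----------------------------------------------------------

    def ingest_extract(
        self, extract: ExtractDocument, links: Iterable[PatientLink]
    ) -> list[InsertionResult]:
        """Insert one extract's entries as instances.

        Validates first (rejecting the whole extract on any error, leaving
        the repository unchanged), resolves the subject through the link
        table, and is idempotent on ``extract_id``.
        """
        if extract.extract_id in self._seen:
            return list(self._seen[extract.extract_id])
        report = validate_extract(extract, self.registry, self.mapping)
        if not report.valid:
            raise IngestValidationError(report)
        link_map = {l.app_patient_id: l.study_id for l in links}
        study_id = link_map.get(extract.subject_id)
        if study_id is None:
            raise LinkageError(
                f"subject {extract.subject_id!r} not present in patient link table"
            )
        results: list[InsertionResult] = []
        extract = canonicalize(extract)
        for entry in extract.entries:
            arch = self.registry[entry.archetype_id]
            rc = self._next_rc
            self._next_rc += 1
            inst = INST[f"rec{rc:06d}"]
            g = self.graph
            g.add((inst, RDF.type, _class_iri(arch.concept)))
            g.add((inst, ONTO.rc_id, Literal(rc)))
            g.add((inst, ONTO.subject_id, Literal(study_id)))
            g.add((inst, ONTO.app_subject_id, Literal(extract.subject_id)))
            g.add((inst, ONTO.from_extract, Literal(extract.extract_id)))
            for el in entry.elements:
                self._add_element(inst, el)
            results.append(InsertionResult(rc_id=rc, iri=str(inst)))
        self._seen[extract.extract_id] = results
        return list(results)

    def _add_element(self, inst: URIRef, el: ElementNode) -> None:
        prop = ONTO[el.name]
        v = el.value
        if isinstance(v, CodedValue):
            binding = self.mapping.binding_for_concept(v.concept_id)
            target = _binding_class_iri(binding.display if binding else v.display)
            self.graph.add((inst, prop, target))
        elif isinstance(v, DateValue):
            self.graph.add((inst, prop, Literal(v.value, datatype=XSD.date)))
        elif isinstance(v, QuantityValue):
            self.graph.add(
                (inst, prop, Literal(Decimal(repr(v.magnitude)), datatype=XSD.decimal))
            )
        else:
            self.graph.add((inst, prop, Literal(v.value)))

    # -- reporting -----------------------------------------------------------

    @property
    def instance_count(self) -> int:
        return len(set(self.graph.subjects(ONTO.rc_id, None)))

    def _instances_of(self, archetype_id: str) -> list[URIRef]:
        cls = _class_iri(self.registry[archetype_id].concept)
        return [s for s in self.graph.subjects(RDF.type, cls)
                if (s, ONTO.rc_id, None) in self.graph]

    def count_report(self, total_users: int) -> RepositoryReport:
        """Per-archetype extract counts and shares, plus distinct patients
        with ≥1 extract as a share of ``total_users`` (passed explicitly:
        never-users leave no trace in the repository)."""
        per_arch = {}
        total = 0
        for aid in sorted(self.registry):
            insts = self._instances_of(aid)
            patients = {
                str(self.graph.value(i, ONTO.app_subject_id)) for i in insts
            }
            per_arch[aid] = (len(insts), len(patients))
            total += len(insts)
        stats = tuple(
            ArchetypeStats(
                archetype_id=aid,
                n_extracts=n,
                pct_extracts=pct(n, total),
                n_patients=p,
                pct_patients=pct(p, total_users),
            )
            for aid, (n, p) in per_arch.items()
        )
        return RepositoryReport(
            total_extracts=total, total_users=total_users, per_archetype=stats
        )

    # -- export --------------------------------------------------------------

    def export_extract(self, extract_id: str) -> ExtractDocument:
        """Reconstruct an extract from the instance data in the graph
        (repository→extract round trip)."""
        insts = sorted(
            self.graph.subjects(ONTO.from_extract, Literal(extract_id)),
            key=lambda s: int(self.graph.value(s, ONTO.rc_id)),
        )
        if not insts:
            raise RepositoryError(f"no instances for extract {extract_id!r}")
        subject = str(self.graph.value(insts[0], ONTO.app_subject_id))
        entries = []
        for inst in insts:
            cls = next(
                c for c in self.graph.objects(inst, RDF.type)
                if (c, RDFS.subClassOf, ONTO.ENTRY) in self.graph
            )
            aid = str(self.graph.value(cls, ONTO.archetype_id))
            arch = self.registry[aid]
            elements = []
            for idx, c in enumerate(arch.constraints):
                obj = self.graph.value(inst, ONTO[c.name])
                if obj is None:
                    continue
                elements.append(
                    ElementNode(
                        node_id=f"at{idx + 1:04d}",
                        name=c.name,
                        value=self._value_from_graph(c, obj),
                    )
                )
            entries.append(
                EntryNode(
                    archetype_id=aid,
                    elements=tuple(elements),
                    rc_id=int(self.graph.value(inst, ONTO.rc_id)),
                )
            )
        first_date = next(
            (el.value.value for e in entries for el in e.elements
             if isinstance(el.value, DateValue)),
            _dt.date(1970, 1, 1),
        )
        return canonicalize(
            ExtractDocument(
                extract_id=extract_id,
                subject_id=subject,
                time_created=_dt.datetime(
                    first_date.year, first_date.month, first_date.day,
                    tzinfo=_dt.timezone.utc,
                ),
                entries=tuple(entries),
            )
        )

    def _value_from_graph(self, constraint, obj):
        if constraint.value_kind == "coded":
            cid = str(self.graph.value(obj, ONTO.concept_id))
            display = str(self.graph.value(obj, RDFS.label) or "")
            return CodedValue(
                concept_id=cid, scheme_uri=self.mapping.scheme_uri, display=display
            )
        if constraint.value_kind == "date":
            return DateValue(value=_dt.date.fromisoformat(str(obj)))
        if constraint.value_kind == "quantity":
            return QuantityValue(magnitude=float(obj), unit=constraint.unit)
        return TextValue(value=str(obj))

    # -- persistence ---------------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        self.graph.serialize(destination=str(path), format="turtle")

    @classmethod
    def load(
        cls,
        path: Union[str, Path],
        registry: Mapping[str, EntryArchetype],
        mapping: MappingConfig,
    ) -> "OntologyRepository":
        g = Graph()
        g.parse(str(path), format="turtle")
        return cls(registry, mapping, graph=g)
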