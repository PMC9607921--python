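"""In-memory subset of the EN/ISO 13606 reference model.

The dual-model architecture separates a stable *reference model* — generic
record structures such as the EHR extract, the entry (one observation or
clinical action) and the element (a leaf node holding a single data value) —
from *archetypes*, which constrain those structures per clinical concept.
This module implements the reference-model side for the two entry types the
pipeline carries (side effects and daily activity): four data-value kinds,
elements, entries and the extract document, plus a canonicalization pass
that makes serialization deterministic.

The COMPOSITION/SECTION/CLUSTER layers of the full standard are collapsed:
extracts here carry entries directly, which is all two flat four-element
entries need.
"""

from __future__ import annotations

import datetime as _dt
from typing import Mapping, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "CodedValue",
    "DateValue",
    "QuantityValue",
    "TextValue",
    "DataValue",
    "ElementNode",
    "EntryNode",
    "ExtractDocument",
    "ReferenceModelError",
    "build_entry",
    "canonicalize",
    "ARCHETYPE_ELEMENT_ORDER",
]


class ReferenceModelError(ValueError):
    """Raised when a reference-model structure cannot be built."""


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid", revalidate_instances="always")


class CodedValue(_Frozen):
    """A terminology-coded value: concept identifier, coding-scheme URI and
    a human-readable display (which may be a Spanish app literal)."""

    concept_id: str
    scheme_uri: str
    display: str = ""

    @field_validator("scheme_uri")
    @classmethod
    def _scheme_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("scheme_uri must be non-empty")
        return v

    @model_validator(mode="after")
    def _snomed_concept_ids_are_digits(self) -> "CodedValue":
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")
        if "snomed" in self.scheme_uri.lower() and not self.concept_id.isdigit():
            raise ValueError(
                f"SNOMED CT concept_id must be all digits, got {self.concept_id!r}"
            )
        return self


class DateValue(_Frozen):
    """A calendar date at day precision (ISO 8601)."""

    value: _dt.date

    @field_validator("value", mode="before")
    @classmethod
    def _parse(cls, v):
        if isinstance(v, _dt.datetime):
            return v.date()
        if isinstance(v, str):
            return _dt.date.fromisoformat(v)
        return v


class QuantityValue(_Frozen):
    """A non-negative magnitude with a unit (e.g. steps, kcal, min)."""

    magnitude: float
    unit: str

    @field_validator("magnitude")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("magnitude must be >= 0")
        return float(v)

    @field_validator("unit")
    @classmethod
    def _unit_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("unit must be non-empty")
        return v


class TextValue(_Frozen):
    """Free text."""

    value: str


DataValue = Union[CodedValue, DateValue, QuantityValue, TextValue]


class ElementNode(_Frozen):
    """Leaf node of the record hierarchy: one named slot holding exactly one
    data value, tagged with its archetype node identifier (``at0001``...)."""

    node_id: str
    name: str
    value: DataValue


class EntryNode(_Frozen):
    """One clinical observation or action: an ordered list of elements
    governed by a single archetype.  ``rc_id`` is the repository-assigned
    record identifier, absent until ingestion."""

    archetype_id: str
    elements: tuple[ElementNode, ...]
    rc_id: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "EntryNode":
        if not self.elements:
            raise ValueError("entry must contain at least one element")
        names = [e.name for e in self.elements]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate element names in entry: {names}")
        node_ids = [e.node_id for e in self.elements]
        if len(set(node_ids)) != len(node_ids):
            raise ValueError(f"duplicate node_ids in entry: {node_ids}")
        return self


class ExtractDocument(_Frozen):
    """An EHR extract: the unit of communication between the app side and
    the repository.  ``subject_id`` is the pseudonymous app-side patient
    identifier — hospital identifiers never appear in an extract."""

    extract_id: str
    subject_id: str
    time_created: _dt.datetime
    entries: tuple[EntryNode, ...]

    @model_validator(mode="after")
    def _check(self) -> "ExtractDocument":
        if not self.extract_id:
            raise ValueError("extract_id must be non-empty")
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if not self.entries:
            raise ValueError("extract must contain at least one entry")
        return self


#: Element declaration order of the two built-in archetypes.  node_ids are
#: assigned from this order; the archetype registry mirrors it.
ARCHETYPE_ELEMENT_ORDER: dict[str, tuple[str, ...]] = {
    "side_effect": ("date", "finding", "value", "severity"),
    "daily_activity": ("date", "steps", "calories", "duration"),
}


def _node_id(ordinal: int) -> str:
    return f"at{ordinal:04d}"


def build_entry(
    archetype_id: str,
    values: Mapping[str, DataValue],
    element_order: Optional[Sequence[str]] = None,
) -> EntryNode:
    """Build an entry from a name→value mapping.

    node_ids are assigned deterministically: ``at0001``... by position in the
    archetype's declared element order (falling back to the mapping's own
    order for archetypes without a registered order).  Unknown names keep
    their relative order after the declared ones.

    Raises :class:`ReferenceModelError` on duplicate or empty input.
    """
    names = list(values)
    if len(set(names)) != len(names):
        raise ReferenceModelError(f"duplicate element names: {names}")
    if not names:
        raise ReferenceModelError("cannot build an entry with no elements")
    order = list(
        element_order
        if element_order is not None
        else ARCHETYPE_ELEMENT_ORDER.get(archetype_id, names)
    )
    rank = {n: i for i, n in enumerate(order)}
    ordered = sorted(names, key=lambda n: (rank.get(n, len(order)), n))
    elements = tuple(
        ElementNode(node_id=_node_id(rank.get(n, i) + 1), name=n, value=values[n])
        for i, n in enumerate(ordered)
    )
    try:
        return EntryNode(archetype_id=archetype_id, elements=elements)
    except ValueError as exc:  # duplicate node_ids from a pathological order
        raise ReferenceModelError(str(exc)) from exc


def _entry_sort_key(entry: EntryNode):
    first_date = ""
    for el in entry.elements:
        if isinstance(el.value, DateValue):
            first_date = el.value.value.isoformat()
            break
    rc = "" if entry.rc_id is None else f"{entry.rc_id:012d}"
    # full-content tie-break so equal-key entries still order deterministically
    fingerprint = repr(
        sorted((el.node_id, el.name, repr(el.value)) for el in entry.elements)
    )
    return (entry.archetype_id, first_date, rc, fingerprint)


def canonicalize(extract: ExtractDocument) -> ExtractDocument:
    """Return the canonical form of an extract.

    Entries are sorted by (archetype_id, first date-valued element, rc_id);
    elements within an entry are sorted by node_id, i.e. archetype
    declaration order.  Idempotent and invariant under permutation of the
    input's entry order.
    """
    entries = tuple(
        EntryNode(
            archetype_id=e.archetype_id,
            elements=tuple(sorted(e.elements, key=lambda el: (el.node_id, el.name))),
            rc_id=e.rc_id,
        )
        for e in sorted(extract.entries, key=_entry_sort_key)
    )
    return ExtractDocument(
        extract_id=extract.extract_id,
        subject_id=extract.subject_id,
        time_created=extract.time_created,
        entries=entries,
    )
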