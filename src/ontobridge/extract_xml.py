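"""Bit-stable XML serialization of extract documents — the wire format.

The dialect is this artifact's own, fixed and versioned (namespace
``urn:ontobridge:extract:1``) and published as an XSD shipped with the
package: ``ehrExtract`` carrying ``entry`` elements (attribute
``archetypeId``, optional ``rcId``), each carrying ``element`` leaves
(``nodeId``, ``name``) with an explicitly ``kind``-tagged ``value``.

Serialization is deterministic by construction: the document is
canonicalized first, encoding is UTF-8 with LF line endings and 2-space
indentation, and attributes are written in a fixed order.  No timestamp is
injected at write time — ``timeCreated`` comes from the document — so
writing the same extract twice yields byte-identical files, which is what
makes dedupe-by-content-hash work downstream.
"""

from __future__ import annotations

import datetime as _dt
import importlib.resources
from typing import Union

from lxml import etree

from .reference_model import (
    CodedValue,
    DataValue,
    DateValue,
    ElementNode,
    EntryNode,
    ExtractDocument,
    QuantityValue,
    TextValue,
    canonicalize,
)

__all__ = [
    "NAMESPACE",
    "ExtractParseError",
    "ExtractSchemaError",
    "SerializationError",
    "write_extract",
    "read_extract",
    "schema",
]

NAMESPACE = "urn:ontobridge:extract:1"
_NS = f"{{{NAMESPACE}}}"


class ExtractParseError(ValueError):
    """Input is not well-formed XML (message carries line/column)."""


class ExtractSchemaError(ValueError):
    """Well-formed XML that violates the extract schema."""


class SerializationError(ValueError):
    """The in-memory document is not structurally valid for writing."""


_schema_cache: etree.XMLSchema | None = None


def schema() -> etree.XMLSchema:
    """The compiled XSD for the extract dialect."""
    global _schema_cache
    if _schema_cache is None:
        text = (
            importlib.resources.files("ontobridge.data")
            .joinpath("extract.xsd")
            .read_text(encoding="utf-8")
        )
        _schema_cache = etree.XMLSchema(etree.fromstring(text.encode("utf-8")))
    return _schema_cache


def _format_magnitude(m: float) -> str:
    return str(int(m)) if float(m).is_integer() else repr(float(m))


def _value_to_xml(parent: etree._Element, value: DataValue) -> None:
    el = etree.SubElement(parent, f"{_NS}value")
    if isinstance(value, CodedValue):
        el.set("kind", "coded")
        el.set("conceptId", value.concept_id)
        el.set("schemeUri", value.scheme_uri)
        el.text = value.display
    elif isinstance(value, DateValue):
        el.set("kind", "date")
        el.text = value.value.isoformat()
    elif isinstance(value, QuantityValue):
        el.set("kind", "quantity")
        el.set("unit", value.unit)
        el.text = _format_magnitude(value.magnitude)
    else:
        el.set("kind", "text")
        el.text = value.value


def write_extract(extract: ExtractDocument) -> bytes:
    """Serialize an extract to canonical UTF-8 XML bytes.

    The output is schema-valid and byte-stable across runs; a structurally
    invalid document is refused with :class:`SerializationError`.
    """
    try:
        extract = canonicalize(_revalidate(extract))
    except ValueError as exc:
        raise SerializationError(str(exc)) from exc
    root = etree.Element(f"{_NS}ehrExtract", nsmap={None: NAMESPACE})
    root.set("extractId", extract.extract_id)
    root.set("subjectId", extract.subject_id)
    tc = extract.time_created
    if tc.tzinfo is None:
        tc = tc.replace(tzinfo=_dt.timezone.utc)
    root.set("timeCreated", tc.astimezone(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"))
    for entry in extract.entries:
        e = etree.SubElement(root, f"{_NS}entry")
        e.set("archetypeId", entry.archetype_id)
        if entry.rc_id is not None:
            e.set("rcId", str(entry.rc_id))
        for element in entry.elements:
            x = etree.SubElement(e, f"{_NS}element")
            x.set("nodeId", element.node_id)
            x.set("name", element.name)
            _value_to_xml(x, element.value)
    data = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    doc = etree.fromstring(data)
    if not schema().validate(doc):
        raise SerializationError(
            "serialized document violates schema: "
            + "; ".join(str(e) for e in schema().error_log)
        )
    return data


def _revalidate(extract: ExtractDocument) -> ExtractDocument:
    """Re-run the model validators so documents assembled without
    validation (e.g. via model_construct) are refused at the wire."""
    return ExtractDocument(
        extract_id=extract.extract_id,
        subject_id=extract.subject_id,
        time_created=extract.time_created,
        entries=tuple(
            EntryNode(
                archetype_id=e.archetype_id, elements=e.elements, rc_id=e.rc_id
            )
            for e in extract.entries
        ),
    )


_KIND_ATTRS = {
    "coded": {"conceptId", "schemeUri"},
    "date": set(),
    "quantity": {"unit"},
    "text": set(),
}


def _value_from_xml(el: etree._Element, path: str) -> DataValue:
    kind = el.get("kind")
    present = {a for a in ("conceptId", "schemeUri", "unit") if el.get(a) is not None}
    allowed = _KIND_ATTRS[kind]
    if present - allowed:
        raise ExtractSchemaError(
            f"{path}: attributes {sorted(present - allowed)} not allowed on "
            f"kind={kind!r} value"
        )
    text = el.text or ""
    try:
        if kind == "coded":
            if present != allowed:
                raise ValueError("coded value requires conceptId and schemeUri")
            return CodedValue(
                concept_id=el.get("conceptId"),
                scheme_uri=el.get("schemeUri"),
                display=text,
            )
        if kind == "date":
            return DateValue(value=_dt.date.fromisoformat(text))
        if kind == "quantity":
            if "unit" not in present:
                raise ValueError("quantity value requires a unit")
            return QuantityValue(magnitude=float(text), unit=el.get("unit"))
        return TextValue(value=text)
    except (ValueError, TypeError) as exc:
        raise ExtractSchemaError(f"{path}: {exc}") from exc


def read_extract(data: Union[bytes, str]) -> ExtractDocument:
    """Parse and schema-validate XML bytes into a canonical extract.

    Unknown elements or attributes are rejected (strict dialect).  Raises
    :class:`ExtractParseError` for malformed XML and
    :class:`ExtractSchemaError` for schema violations, listing paths.
    """
    if isinstance(data, str):
        data = data.encode("utf-8")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ExtractParseError(f"malformed XML: {exc}") from exc
    if not schema().validate(root):
        raise ExtractSchemaError(
            "schema violation: "
            + "; ".join(
                f"line {e.line}: {e.message}" for e in schema().error_log
            )
        )
    entries = []
    for i, e in enumerate(root.findall(f"{_NS}entry")):
        elements = []
        for x in e.findall(f"{_NS}element"):
            path = f"entries[{i}]/{x.get('name')}"
            elements.append(
                ElementNode(
                    node_id=x.get("nodeId"),
                    name=x.get("name"),
                    value=_value_from_xml(x.find(f"{_NS}value"), path),
                )
            )
        rc = e.get("rcId")
        try:
            entries.append(
                EntryNode(
                    archetype_id=e.get("archetypeId"),
                    elements=tuple(elements),
                    rc_id=None if rc is None else int(rc),
                )
            )
        except ValueError as exc:
            raise ExtractSchemaError(f"entries[{i}]: {exc}") from exc
    try:
        doc = ExtractDocument(
            extract_id=root.get("extractId"),
            subject_id=root.get("subjectId"),
            time_created=_dt.datetime.fromisoformat(
                root.get("timeCreated").replace("Z", "+00:00")
            ),
            entries=tuple(entries),
        )
    except ValueError as exc:
        raise ExtractSchemaError(str(exc)) from exc
    return canonicalize(doc)
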