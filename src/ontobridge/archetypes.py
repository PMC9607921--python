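"""Archetype model: declarative constraint definitions and their validator.

Archetypes are the knowledge half of the dual model: each one constrains a
reference-model entry for a single clinical concept (element names, value
kinds, required/optional, units for quantities, terminology bindings for
coded values).  They are bundled as YAML documents rather than ADL, keeping
constraints in data, not code; user-supplied archetype files can be loaded
from arbitrary paths to add new concepts without touching the package.

The content model is *closed*: elements not declared by the archetype are
validation errors.  Multi-occurrence elements are not supported.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal, Mapping, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .reference_model import (
    CodedValue,
    DateValue,
    EntryNode,
    ExtractDocument,
    QuantityValue,
    TextValue,
)
from .terminology import MappingConfig

__all__ = [
    "ElementConstraint",
    "EntryArchetype",
    "ValidationIssue",
    "ValidationReport",
    "ArchetypeError",
    "load_archetype",
    "builtin_registry",
    "validate_entry",
    "validate_extract",
]

ValueKind = Literal["coded", "date", "quantity", "text"]

_KIND_OF_TYPE = {
    CodedValue: "coded",
    DateValue: "date",
    QuantityValue: "quantity",
    TextValue: "text",
}


class ArchetypeError(ValueError):
    """Malformed archetype definition or misuse of the validator."""


class ElementConstraint(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    value_kind: ValueKind
    required: bool = True
    #: name of the mapping-config section whose codes are admissible
    binding: Optional[str] = None
    #: required unit, present iff value_kind == "quantity"
    unit: Optional[str] = None

    @model_validator(mode="after")
    def _consistency(self) -> "ElementConstraint":
        if (self.value_kind == "quantity") != (self.unit is not None):
            raise ValueError(f"{self.name}: unit present iff value_kind=quantity")
        if self.binding is not None and self.value_kind != "coded":
            raise ValueError(f"{self.name}: binding only allowed for coded elements")
        return self


class EntryArchetype(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    archetype_id: str
    concept: str
    constraints: tuple[ElementConstraint, ...]

    @model_validator(mode="after")
    def _check(self) -> "EntryArchetype":
        if not self.constraints:
            raise ValueError("archetype must declare at least one element")
        names = [c.name for c in self.constraints]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate constraint names: {names}")
        return self

    @property
    def element_order(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.constraints)

    def constraint(self, name: str) -> Optional[ElementConstraint]:
        for c in self.constraints:
            if c.name == name:
                return c
        return None


class ValidationIssue(BaseModel):
    model_config = ConfigDict(frozen=True)

    severity: Literal["error", "warning"]
    path: str
    message: str


class ValidationReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    issues: tuple[ValidationIssue, ...] = ()

    @property
    def valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "error")

    def __add__(self, other: "ValidationReport") -> "ValidationReport":
        return ValidationReport(issues=self.issues + other.issues)


def load_archetype(source: Union[str, Path]) -> EntryArchetype:
    """Load one archetype definition from a YAML (or JSON) document."""
    text = Path(source).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ArchetypeError(f"{source}: archetype document must be a mapping")
    try:
        return EntryArchetype.model_validate(data)
    except ValueError as exc:
        raise ArchetypeError(f"{source}: {exc}") from exc


def builtin_registry() -> dict[str, EntryArchetype]:
    """The two bundled archetypes: ``side_effect`` (date, finding, value,
    severity) and ``daily_activity`` (date, steps, calories, duration)."""
    registry: dict[str, EntryArchetype] = {}
    root = importlib.resources.files("ontobridge.data").joinpath("archetypes")
    for name in ("side_effect.yaml", "daily_activity.yaml"):
        arch = EntryArchetype.model_validate(
            yaml.safe_load(root.joinpath(name).read_text(encoding="utf-8"))
        )
        registry[arch.archetype_id] = arch
    return registry


def _err(path: str, message: str) -> ValidationIssue:
    return ValidationIssue(severity="error", path=path, message=message)


def validate_entry(
    entry: EntryNode,
    archetype: EntryArchetype,
    mapping: Optional[MappingConfig] = None,
) -> ValidationReport:
    """Check one entry against its archetype.

    Flags missing required elements, unexpected element names (closed
    content), value-kind mismatches, unit mismatches, and coded values whose
    concept_id is outside the bound value set.  A terminology-binding miss
    is an error, not a warning: the pipeline exists to emit coded data.

    Raises :class:`ArchetypeError` if the entry cites a different archetype
    (a usage error, distinct from a validation failure).
    """
    if entry.archetype_id != archetype.archetype_id:
        raise ArchetypeError(
            f"entry cites archetype {entry.archetype_id!r}, "
            f"validator was given {archetype.archetype_id!r}"
        )
    base = f"entry[{archetype.archetype_id}]"
    issues: list[ValidationIssue] = []
    present = {el.name: el for el in entry.elements}

    for c in archetype.constraints:
        if c.required and c.name not in present:
            issues.append(_err(f"{base}/{c.name}", "required element missing"))
    for el in entry.elements:
        path = f"{base}/{el.name}"
        c = archetype.constraint(el.name)
        if c is None:
            issues.append(_err(path, "unexpected element (closed content model)"))
            continue
        kind = _KIND_OF_TYPE[type(el.value)]
        if kind != c.value_kind:
            issues.append(
                _err(path, f"value kind {kind!r} does not match declared {c.value_kind!r}")
            )
            continue
        if isinstance(el.value, QuantityValue) and el.value.unit != c.unit:
            issues.append(
                _err(path, f"unit {el.value.unit!r} does not match declared {c.unit!r}")
            )
        if isinstance(el.value, CodedValue) and c.binding is not None:
            if mapping is None:
                issues.append(
                    _err(path, f"no mapping config supplied to check binding {c.binding!r}")
                )
            elif not mapping.contains_concept(c.binding, el.value.concept_id):
                issues.append(
                    _err(
                        path,
                        f"concept_id {el.value.concept_id!r} not in bound "
                        f"value set {c.binding!r}",
                    )
                )
    return ValidationReport(issues=tuple(issues))


def validate_extract(
    extract: ExtractDocument,
    registry: Mapping[str, EntryArchetype],
    mapping: Optional[MappingConfig] = None,
) -> ValidationReport:
    """Validate a whole extract: per-entry archetype conformance plus
    extract-level checks.  All problems are reported, none raised."""
    issues: list[ValidationIssue] = []
    if not extract.subject_id:
        issues.append(_err("extract", "missing subject_id"))
    if not extract.entries:
        issues.append(_err("extract", "extract has no entries"))
    report = ValidationReport(issues=tuple(issues))
    for i, entry in enumerate(extract.entries):
        arch = registry.get(entry.archetype_id)
        if arch is None:
            report = report + ValidationReport(
                issues=(
                    _err(f"entries[{i}]", f"unknown archetype {entry.archetype_id!r}"),
                )
            )
            continue
        report = report + validate_entry(entry, arch, mapping)
    return report
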