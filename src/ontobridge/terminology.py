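"""SNOMED CT binding layer.

The app database stores uncoded Spanish literals; semantic normalization
happens here, by resolving each local label against a JSON mapping config
that carries the SNOMED CT concept ID, concept URI and preferred term for
every admissible finding and severity.  Resolution is a pure, total lookup
over the config's label set — an unmapped literal raises
:class:`UnmappedTermError` so the conversion pipeline fails loudly rather
than emit uncoded data.

Labels are normalized before lookup (trimmed, whitespace-collapsed,
lowercased, accents folded via NFKD) because the app imposes no casing or
accent convention on its literals.
"""

from __future__ import annotations

import json
import logging
import unicodedata
from pathlib import Path
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "SNOMED_SCHEME_URI",
    "TermBinding",
    "MappingConfig",
    "MappingConfigError",
    "UnmappedTermError",
    "normalize_label",
    "load_mapping",
    "builtin_mapping_path",
    "resolve",
]

logger = logging.getLogger(__name__)

#: Standard SNOMED CT URI scheme; concept URIs are ``<scheme>/id/<conceptId>``.
SNOMED_SCHEME_URI = "http://snomed.info/sct"

Section = Literal["findings", "severities"]


class MappingConfigError(ValueError):
    """Malformed or inconsistent mapping configuration."""


class UnmappedTermError(KeyError):
    """A local literal has no binding in the mapping config."""

    def __init__(self, section: str, label: str):
        self.section = section
        self.label = label
        super().__init__(f"no {section} binding for label {label!r}")

    def __str__(self) -> str:  # KeyError quotes its arg otherwise
        return f"no {self.section} binding for label {self.label!r}"


def normalize_label(label: str) -> str:
    """Canonical lookup form of a local label: NFKD accent-fold, casefold,
    trim and collapse internal whitespace."""
    folded = "".join(
        ch
        for ch in unicodedata.normalize("NFKD", label)
        if not unicodedata.combining(ch)
    )
    return " ".join(folded.casefold().split())


class TermBinding(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    local_label: str
    concept_id: str
    code_uri: str = ""
    display: str = ""

    @field_validator("concept_id")
    @classmethod
    def _digits(cls, v: str) -> str:
        if not v.isdigit():
            raise ValueError(f"concept_id must be all digits, got {v!r}")
        return v

    @model_validator(mode="after")
    def _fill_and_check(self) -> "TermBinding":
        object.__setattr__(self, "display", self.display or self.local_label)
        object.__setattr__(
            self, "code_uri", self.code_uri or f"http://snomed.info/id/{self.concept_id}"
        )
        if not self.code_uri.endswith(self.concept_id):
            raise ValueError(
                f"code_uri {self.code_uri!r} must end with concept_id {self.concept_id!r}"
            )
        return self


class MappingConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    scheme_uri: str = SNOMED_SCHEME_URI
    findings: tuple[TermBinding, ...] = ()
    severities: tuple[TermBinding, ...] = ()

    @model_validator(mode="after")
    def _no_duplicate_labels(self) -> "MappingConfig":
        for section in ("findings", "severities"):
            seen: dict[str, str] = {}
            for b in getattr(self, section):
                key = normalize_label(b.local_label)
                if key in seen:
                    raise ValueError(
                        f"{section}: duplicate local label {b.local_label!r} "
                        f"(collides with {seen[key]!r} after normalization)"
                    )
                seen[key] = b.local_label
        return self

    def section(self, name: Section) -> tuple[TermBinding, ...]:
        if name not in ("findings", "severities"):
            raise MappingConfigError(f"unknown mapping section {name!r}")
        return getattr(self, name)

    def lookup(self, name: Section, label: str) -> Optional[TermBinding]:
        key = normalize_label(label)
        for b in self.section(name):
            if normalize_label(b.local_label) == key:
                return b
        return None

    def contains_concept(self, name: Section, concept_id: str) -> bool:
        return any(b.concept_id == concept_id for b in self.section(name))

    def binding_for_concept(self, concept_id: str) -> Optional[TermBinding]:
        for section in ("findings", "severities"):
            for b in self.section(section):  # type: ignore[arg-type]
                if b.concept_id == concept_id:
                    return b
        return None


def _parse_section(section: str, raw) -> tuple[TermBinding, ...]:
    if raw is None:
        return ()
    if isinstance(raw, dict):
        items = [dict(v, local_label=k) for k, v in raw.items()]
    elif isinstance(raw, list):
        items = raw
    else:
        raise MappingConfigError(f"{section}: expected object or array")
    out = []
    for i, item in enumerate(items):
        try:
            out.append(TermBinding.model_validate(item))
        except ValueError as exc:
            raise MappingConfigError(f"{section}[{i}]: {exc}") from exc
    return tuple(out)


def load_mapping(path: Union[str, Path]) -> MappingConfig:
    """Load and validate a JSON mapping config.

    The document has top-level ``scheme_uri``, ``findings`` and
    ``severities``; each section maps local labels to bindings (see
    ``docs/mapping.schema.json`` for the published schema).  Duplicate
    labels (after normalization) and non-numeric concept IDs are config
    errors; empty sections are legal but logged as a warning.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise MappingConfigError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise MappingConfigError(f"{path}: top level must be a JSON object")
    try:
        config = MappingConfig(
            scheme_uri=raw.get("scheme_uri", SNOMED_SCHEME_URI),
            findings=_parse_section("findings", raw.get("findings")),
            severities=_parse_section("severities", raw.get("severities")),
        )
    except ValueError as exc:
        raise MappingConfigError(f"{path}: {exc}") from exc
    for section in ("findings", "severities"):
        if not getattr(config, section):
            logger.warning("mapping config %s: section %r is empty", path, section)
    return config


def builtin_mapping_path() -> Path:
    """Path of the bundled mapping fixture (see its ``note`` field for
    which codes are real SNOMED CT content)."""
    import importlib.resources

    return Path(str(importlib.resources.files("ontobridge.data") / "mapping.json"))


def resolve(config: MappingConfig, section: Section, label: str) -> TermBinding:
    """Resolve a local literal to its SNOMED CT binding.

    Deterministic and total over the config's label set; raises
    :class:`UnmappedTermError` carrying the offending literal otherwise.
    """
    binding = config.lookup(section, label)
    if binding is None:
        raise UnmappedTermError(section, label)
    return binding
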