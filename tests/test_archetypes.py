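import pytest
from hypothesis import given

from ontobridge.archetypes import (
    ArchetypeError,
    ElementConstraint,
    validate_entry,
    validate_extract,
)
from ontobridge.reference_model import (
    CodedValue,
    DateValue,
    ElementNode,
    EntryNode,
    ExtractDocument,
    QuantityValue,
    TextValue,
    build_entry,
)
from ontobridge.terminology import builtin_mapping_path, load_mapping

from .conftest import side_effect_entries

MAPPING = load_mapping(builtin_mapping_path())


def _side_effect_entry(mapping, *, with_value=True):
    values = {
        "date": DateValue(value="2021-03-01"),
        "finding": CodedValue(
            concept_id="365930002", scheme_uri=mapping.scheme_uri, display="Wakefulness"
        ),
        "severity": CodedValue(
            concept_id="24484000", scheme_uri=mapping.scheme_uri, display="Severe"
        ),
    }
    if with_value:
        values["value"] = TextValue(value="poor sleep")
    return build_entry("side_effect", values)


class TestBuiltinRegistry:
    def test_exactly_two_archetypes(self, registry):
        assert set(registry) == {"side_effect", "daily_activity"}

    def test_side_effect_element_names(self, registry):
        assert registry["side_effect"].element_order == (
            "date",
            "finding",
            "value",
            "severity",
        )

    def test_daily_activity_element_names_and_units(self, registry):
        arch = registry["daily_activity"]
        assert arch.element_order == ("date", "steps", "calories", "duration")
        assert [c.unit for c in arch.constraints] == [None, "steps", "kcal", "min"]

    def test_only_value_element_is_optional(self, registry):
        required = {
            c.name: c.required for a in registry.values() for c in a.constraints
        }
        assert required.pop("value") is False
        assert all(required.values())


class TestElementConstraint:
    def test_unit_requires_quantity_kind(self):
        with pytest.raises(ValueError):
            ElementConstraint(name="date", value_kind="date", unit="min")

    def test_binding_requires_coded_kind(self):
        with pytest.raises(ValueError):
            ElementConstraint(name="steps", value_kind="quantity", unit="steps",
                              binding="findings")


class TestValidateEntry:
    def test_complete_mapped_entry_is_valid(self, registry, mapping):
        report = validate_entry(
            _side_effect_entry(mapping), registry["side_effect"], mapping
        )
        assert report.valid and not report.issues

    def test_missing_required_element_is_an_error_at_its_path(self, registry, mapping):
        entry = build_entry(
            "side_effect",
            {
                "date": DateValue(value="2021-03-01"),
                "severity": CodedValue(
                    concept_id="24484000", scheme_uri=mapping.scheme_uri
                ),
            },
        )
        report = validate_entry(entry, registry["side_effect"], mapping)
        assert not report.valid
        assert [i.path for i in report.errors] == ["entry[side_effect]/finding"]

    def test_missing_optional_value_element_is_fine(self, registry, mapping):
        report = validate_entry(
            _side_effect_entry(mapping, with_value=False),
            registry["side_effect"],
            mapping,
        )
        assert report.valid

    def test_unexpected_element_violates_closed_content(self, registry, mapping):
        base = _side_effect_entry(mapping)
        entry = EntryNode(
            archetype_id="side_effect",
            elements=base.elements
            + (
                ElementNode(
                    node_id="at0099",
                    name="steps",
                    value=QuantityValue(magnitude=1, unit="steps"),
                ),
            ),
        )
        report = validate_entry(entry, registry["side_effect"], mapping)
        assert any("unexpected element" in i.message for i in report.errors)

    def test_value_kind_mismatch_flagged(self, registry, mapping):
        entry = build_entry(
            "side_effect",
            {
                "date": TextValue(value="not a date"),
                "finding": CodedValue(
                    concept_id="365930002", scheme_uri=mapping.scheme_uri
                ),
                "severity": CodedValue(
                    concept_id="24484000", scheme_uri=mapping.scheme_uri
                ),
            },
        )
        report = validate_entry(entry, registry["side_effect"], mapping)
        assert any("value kind" in i.message for i in report.errors)

    def test_unit_mismatch_flagged(self, registry, mapping):
        entry = build_entry(
            "daily_activity",
            {
                "date": DateValue(value="2021-03-01"),
                "steps": QuantityValue(magnitude=10, unit="km"),
                "calories": QuantityValue(magnitude=10, unit="kcal"),
                "duration": QuantityValue(magnitude=10, unit="min"),
            },
        )
        report = validate_entry(entry, registry["daily_activity"], mapping)
        assert any("unit" in i.message for i in report.errors)

    def test_unbound_concept_id_is_a_terminology_error(self, registry, mapping):
        entry = build_entry(
            "side_effect",
            {
                "date": DateValue(value="2021-03-01"),
                "finding": CodedValue(
                    concept_id="1234567", scheme_uri=mapping.scheme_uri
                ),
                "severity": CodedValue(
                    concept_id="24484000", scheme_uri=mapping.scheme_uri
                ),
            },
        )
        report = validate_entry(entry, registry["side_effect"], mapping)
        assert any("value set" in i.message for i in report.errors)

    def test_archetype_mismatch_is_a_usage_error(self, registry, mapping):
        with pytest.raises(ArchetypeError):
            validate_entry(
                _side_effect_entry(mapping), registry["daily_activity"], mapping
            )

    @given(entry=side_effect_entries(MAPPING))
    def test_closed_content_removing_any_required_element_invalidates(self, entry):
        from ontobridge.archetypes import builtin_registry

        registry = builtin_registry()
        arch = registry["side_effect"]
        assert validate_entry(entry, arch, MAPPING).valid
        for el in entry.elements:
            constraint = arch.constraint(el.name)
            remaining = tuple(e for e in entry.elements if e.name != el.name)
            if not remaining:
                continue
            reduced = EntryNode(archetype_id="side_effect", elements=remaining)
            report = validate_entry(reduced, arch, MAPPING)
            assert report.valid == (not constraint.required)


class TestValidateExtract:
    def test_one_valid_entry_of_each_archetype(self, registry, mapping):
        import datetime

        doc = ExtractDocument(
            extract_id="x",
            subject_id="XR-0001",
            time_created=datetime.datetime(2021, 3, 1, tzinfo=datetime.timezone.utc),
            entries=(
                _side_effect_entry(mapping),
                build_entry(
                    "daily_activity",
                    {
                        "date": DateValue(value="2021-03-01"),
                        "steps": QuantityValue(magnitude=100, unit="steps"),
                        "calories": QuantityValue(magnitude=20, unit="kcal"),
                        "duration": QuantityValue(magnitude=5, unit="min"),
                    },
                ),
            ),
        )
        assert validate_extract(doc, registry, mapping).valid

    def test_unknown_archetype_reported_not_raised(self, registry, mapping):
        import datetime

        doc = ExtractDocument(
            extract_id="x",
            subject_id="XR-0001",
            time_created=datetime.datetime(2021, 3, 1, tzinfo=datetime.timezone.utc),
            entries=(
                EntryNode(
                    archetype_id="foo",
                    elements=(
                        ElementNode(
                            node_id="at0001",
                            name="date",
                            value=DateValue(value="2021-03-01"),
                        ),
                    ),
                ),
            ),
        )
        report = validate_extract(doc, registry, mapping)
        assert not report.valid
        assert any("unknown archetype" in i.message for i in report.errors)

    def test_extract_with_zero_entries_invalid(self, registry, mapping):
        import datetime

        doc = ExtractDocument.model_construct(
            extract_id="x",
            subject_id="XR-0001",
            time_created=datetime.datetime(2021, 3, 1, tzinfo=datetime.timezone.utc),
            entries=(),
        )
        report = validate_extract(doc, registry, mapping)
        assert not report.valid
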