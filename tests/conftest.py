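import datetime

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from ontobridge.archetypes import builtin_registry
from ontobridge.conversion import ActivityRecord, SideEffectRecord
from ontobridge.reference_model import (
    CodedValue,
    DateValue,
    ExtractDocument,
    QuantityValue,
    TextValue,
    build_entry,
)
from ontobridge.terminology import builtin_mapping_path, load_mapping

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mapping():
    return load_mapping(builtin_mapping_path())


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


# ---------------------------------------------------------------------------
# hypothesis strategies for archetype-conformant documents
# ---------------------------------------------------------------------------

_dates = st.dates(
    min_value=datetime.date(2020, 12, 22), max_value=datetime.date(2022, 4, 4)
)
_texts = st.text(
    alphabet=st.characters(codec="utf-8", exclude_categories=("Cs", "Cc")),
    min_size=0,
    max_size=40,
)


def side_effect_entries(mapping):
    findings = st.sampled_from(mapping.findings)
    severities = st.sampled_from(mapping.severities)

    def build(date, finding, severity, text):
        values = {
            "date": DateValue(value=date),
            "finding": CodedValue(
                concept_id=finding.concept_id,
                scheme_uri=mapping.scheme_uri,
                display=finding.display,
            ),
            "severity": CodedValue(
                concept_id=severity.concept_id,
                scheme_uri=mapping.scheme_uri,
                display=severity.display,
            ),
        }
        if text is not None:
            values["value"] = TextValue(value=text)
        return build_entry("side_effect", values)

    return st.builds(
        build, _dates, findings, severities, st.one_of(st.none(), _texts)
    )


def activity_entries():
    mags = st.floats(min_value=0, max_value=50000, allow_nan=False, width=32)

    def build(date, steps, kcal, mins):
        return build_entry(
            "daily_activity",
            {
                "date": DateValue(value=date),
                "steps": QuantityValue(magnitude=steps, unit="steps"),
                "calories": QuantityValue(magnitude=kcal, unit="kcal"),
                "duration": QuantityValue(magnitude=mins, unit="min"),
            },
        )

    return st.builds(build, _dates, mags, mags, mags)


def extract_documents(mapping):
    entries = st.lists(
        st.one_of(side_effect_entries(mapping), activity_entries()),
        min_size=1,
        max_size=4,
    )

    def build(eid, subject, date, entry_list):
        return ExtractDocument(
            extract_id=eid,
            subject_id=subject,
            time_created=datetime.datetime(
                date.year, date.month, date.day, tzinfo=datetime.timezone.utc
            ),
            entries=tuple(entry_list),
        )

    ids = st.uuids().map(lambda u: u.hex)
    subjects = st.integers(min_value=1, max_value=9999).map(lambda i: f"XR-{i:04d}")
    return st.builds(build, ids, subjects, _dates, entries)


def side_effect_records(mapping):
    return st.builds(
        SideEffectRecord,
        app_patient_id=st.integers(1, 999).map(lambda i: f"XR-{i:04d}"),
        date=_dates,
        finding_label=st.sampled_from([b.local_label for b in mapping.findings]),
        value_text=st.one_of(st.none(), _texts),
        severity_label=st.sampled_from([b.local_label for b in mapping.severities]),
    )


def activity_records():
    return st.builds(
        ActivityRecord,
        app_patient_id=st.integers(1, 999).map(lambda i: f"XR-{i:04d}"),
        date=_dates,
        steps=st.integers(0, 40000),
        calories=st.floats(0, 5000, allow_nan=False),
        duration=st.floats(0, 1440, allow_nan=False),
    )
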