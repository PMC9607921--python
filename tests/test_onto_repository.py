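import datetime

import pytest
from hypothesis import given
from hypothesis import strategies as st
from rdflib import RDF, RDFS, Literal

from ontobridge.archetypes import validate_extract
from ontobridge.conversion import (
    PatientLink,
    SideEffectRecord,
    batch_daily,
    convert_side_effect,
)
from ontobridge.onto_repository import (
    INST,
    ONTO,
    IngestValidationError,
    LinkageError,
    OntologyRepository,
    build_base_ontology,
    pct,
)
from ontobridge.terminology import MappingConfig, builtin_mapping_path, load_mapping

from .conftest import activity_records, side_effect_records

MAPPING = load_mapping(builtin_mapping_path())

LINKS = [
    PatientLink(app_patient_id=f"XR-{i:04d}", study_id=f"ST-{i:04d}")
    for i in range(1, 1000)
]


@pytest.fixture()
def repo(registry, mapping):
    return OntologyRepository(registry, mapping)


def _se_extract(mapping, patient="XR-0001", day=1):
    record = SideEffectRecord(
        app_patient_id=patient,
        date=datetime.date(2021, 3, day),
        finding_label="Wakefulness",
        severity_label="grave",
        value_text="poor sleep",
    )
    return convert_side_effect(record, mapping)


class TestPct:
    @pytest.mark.parametrize(
        "n,d,expected",
        [
            (234, 1100, 21.3),
            (866, 1100, 78.7),
            (34, 47, 72.3),
            (38, 47, 80.9),
            (12, 62, 19.4),
            (47, 62, 75.8),
            (0, 47, 0.0),
            (1, 1, 100.0),
            (5, 0, 0.0),
        ],
    )
    def test_half_up_one_decimal(self, n, d, expected):
        assert pct(n, d) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            pct(-1, 10)


class TestBaseOntology:
    def test_concept_classes_subclass_entry(self, registry, mapping):
        g = build_base_ontology(registry, mapping)
        assert (ONTO.Secondary_effect, RDFS.subClassOf, ONTO.ENTRY) in g
        assert (ONTO.Daily_activity, RDFS.subClassOf, ONTO.ENTRY) in g

    def test_severe_class_is_snomed_metaclass_instance_with_concept_id(
        self, registry, mapping
    ):
        g = build_base_ontology(registry, mapping)
        assert (ONTO.Severe, RDF.type, ONTO.SnomedCTConcept) in g
        assert g.value(ONTO.Severe, ONTO.concept_id) == Literal("24484000")

    def test_every_binding_gets_code_uri_and_concept_id(self, registry, mapping):
        g = build_base_ontology(registry, mapping)
        bound = set(g.subjects(RDF.type, ONTO.SnomedCTConcept))
        n_bindings = len({b.display for b in mapping.findings + mapping.severities})
        assert len(bound) == n_bindings
        for cls in bound:
            assert g.value(cls, ONTO.concept_id) is not None
            assert g.value(cls, ONTO.code_uri) is not None

    def test_empty_inputs_leave_only_the_iso_layer(self):
        g = build_base_ontology({}, MappingConfig())
        assert (ONTO.ENTRY, RDFS.label, None) in g
        assert not list(g.subjects(RDFS.subClassOf, ONTO.ENTRY))


class TestIngest:
    def test_side_effect_instance_has_all_properties(self, repo, mapping):
        results = repo.ingest_extract(_se_extract(mapping), LINKS)
        assert len(results) == 1
        inst = INST[f"rec{results[0].rc_id:06d}"]
        for prop in (ONTO.date, ONTO.finding, ONTO.value, ONTO.severity, ONTO.rc_id):
            assert repo.graph.value(inst, prop) is not None

    def test_subject_resolved_to_study_id(self, repo, mapping):
        results = repo.ingest_extract(_se_extract(mapping), LINKS)
        inst = INST[f"rec{results[0].rc_id:06d}"]
        assert str(repo.graph.value(inst, ONTO.subject_id)) == "ST-0001"

    def test_reingesting_is_a_noop_returning_original_results(self, repo, mapping):
        extract = _se_extract(mapping)
        first = repo.ingest_extract(extract, LINKS)
        count = repo.instance_count
        second = repo.ingest_extract(extract, LINKS)
        assert second == first
        assert repo.instance_count == count

    def test_unlinked_subject_leaves_repository_unchanged(self, repo, mapping):
        extract = _se_extract(mapping, patient="XR-9999")
        before = len(repo.graph)
        with pytest.raises(LinkageError):
            repo.ingest_extract(extract, LINKS[:5])
        assert len(repo.graph) == before

    def test_invalid_extract_rejected_with_report(self, repo, mapping):
        extract = _se_extract(mapping)
        bad = extract.model_copy(
            update={
                "entries": (
                    extract.entries[0].model_copy(update={"archetype_id": "foo"}),
                )
            }
        )
        with pytest.raises(IngestValidationError) as exc:
            repo.ingest_extract(bad, LINKS)
        assert not exc.value.report.valid

    def test_rc_ids_unique_and_monotonic(self, repo, mapping):
        rc_ids = []
        for day in range(1, 6):
            rc_ids += [
                r.rc_id for r in repo.ingest_extract(_se_extract(mapping, day=day), LINKS)
            ]
        assert rc_ids == sorted(rc_ids) and len(set(rc_ids)) == len(rc_ids)

    @given(
        records=st.lists(
            st.one_of(side_effect_records(MAPPING), activity_records()),
            max_size=10,
        )
    )
    def test_conservation_instance_count_equals_distinct_ingested_entries(self, records):
        from ontobridge.archetypes import builtin_registry

        repo = OntologyRepository(builtin_registry(), MAPPING)
        batch = batch_daily(records, MAPPING)
        seen = set()
        expected = 0
        for x in batch.extracts:
            repo.ingest_extract(x, LINKS)
            repo.ingest_extract(x, LINKS)  # idempotent re-send
            if x.extract_id not in seen:
                seen.add(x.extract_id)
                expected += len(x.entries)
        assert repo.instance_count == expected


class TestReport:
    def test_empty_repository_all_zero(self, repo):
        report = repo.count_report(total_users=47)
        assert report.total_extracts == 0
        assert all(
            s.n_extracts == 0 and s.pct_extracts == 0.0 for s in report.per_archetype
        )

    def test_single_type_repository_is_100_percent(self, repo, mapping):
        repo.ingest_extract(_se_extract(mapping), LINKS)
        by_id = {
            s.archetype_id: s for s in repo.count_report(total_users=47).per_archetype
        }
        assert by_id["side_effect"].pct_extracts == 100.0
        assert by_id["daily_activity"].pct_extracts == 0.0

    @given(
        records=st.lists(
            st.one_of(side_effect_records(MAPPING), activity_records()),
            min_size=1,
            max_size=15,
        )
    )
    def test_extract_percentages_sum_to_100(self, records):
        from ontobridge.archetypes import builtin_registry

        repo = OntologyRepository(builtin_registry(), MAPPING)
        for x in batch_daily(records, MAPPING).extracts:
            repo.ingest_extract(x, LINKS)
        report = repo.count_report(total_users=47)
        if report.total_extracts:
            assert sum(s.pct_extracts for s in report.per_archetype) == pytest.approx(
                100.0, abs=0.1
            )


class TestExportRoundTrip:
    @given(
        records=st.lists(
            st.one_of(side_effect_records(MAPPING), activity_records()),
            min_size=1,
            max_size=8,
        )
    )
    def test_exported_extracts_revalidate(self, records):
        from ontobridge.archetypes import builtin_registry

        registry = builtin_registry()
        repo = OntologyRepository(registry, MAPPING)
        for x in batch_daily(records, MAPPING).extracts:
            repo.ingest_extract(x, LINKS)
            exported = repo.export_extract(x.extract_id)
            assert validate_extract(exported, registry, MAPPING).valid
            assert exported.subject_id == x.subject_id

    def test_persistence_round_trip_preserves_state(self, repo, mapping, tmp_path, registry):
        extract = _se_extract(mapping)
        results = repo.ingest_extract(extract, LINKS)
        path = tmp_path / "repo.ttl"
        repo.save(path)
        loaded = OntologyRepository.load(path, registry, mapping)
        assert loaded.instance_count == 1
        # idempotency and rc_id numbering survive a save/load cycle
        assert loaded.ingest_extract(extract, LINKS) == results
        new = loaded.ingest_extract(_se_extract(mapping, day=2), LINKS)
        assert new[0].rc_id == results[0].rc_id + 1
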