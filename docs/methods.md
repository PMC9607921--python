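# Methods

## The dual model and what this package implements

EN/ISO 13606 separates a generic *reference model* — the structures an EHR
extract is made of — from *archetypes*, formal constraint definitions of
individual clinical concepts. The payoff is that a repository can accept a
new concept by adding an archetype (data), not by changing schemas (code).
`ontobridge` implements both halves for a PGHD pipeline plus the systems
around them: terminology binding, a wire format, an ontology repository,
and a cohort simulator.

### Reference-model subset

Only `EHR_EXTRACT`, `ENTRY` and `ELEMENT` are modeled, with four data-value
kinds (coded, date, quantity, text). The intermediate
COMPOSITION/SECTION/CLUSTER layers of the full standard are deliberately
collapsed: both bundled entry types are flat lists of four elements and
need no internal hierarchy. Versioning, attestations, folders and links
are out of scope.

Node identifiers follow the `atNNNN` convention, assigned by position in
the archetype's declared element order, so an entry built from the same
archetype always carries the same node ids regardless of input ordering.
Dates are day-precision ISO 8601; timestamps are UTC ISO 8601 with seconds.
Daily-activity units are fixed as `steps`, `kcal`, `min`.

### Archetypes and validation

Archetypes ship as YAML documents (one per concept) rather than ADL: the
constraint content needed here — element name, value kind,
required/optional, unit, terminology binding — fits a small declarative
schema, and keeping it in data preserves the dual-model separation while
staying self-contained. ADL parsing, specialization and multi-occurrence
elements are not supported.

The content model is **closed**: an element not declared by the archetype
is an error, matching the archetype semantics of constraining rather than
extending. The side-effect `value` element is optional free text; the
other seven elements are required. A coded value whose concept ID is not
in the bound section of the mapping config is an *error*, not a warning,
because emitting uncoded or mis-coded data would defeat the pipeline's
purpose.

### Terminology binding

Local literals are Spanish app strings with no casing or accent
convention, so lookups normalize with NFKD accent-folding, casefold, trim
and whitespace collapse. Resolution is a pure total lookup over the
config; an unmapped literal raises immediately. Concept URIs use the
standard SNOMED CT scheme `http://snomed.info/id/<conceptId>`.

The bundled mapping fixture contains 12 findings and 3 severities. Only
the Wakefulness binding (365930002) and the three severity codes are real
SNOMED CT content; the remaining finding codes are synthetic placeholders
(99xxxxx) standing in for an unpublished production value set, and the
fixture says so in its `note` field.

### Conversion and the wire format

Each app record becomes one single-entry extract ("daily" granularity, one
per patient/date/type), chosen over day-bundling for idempotent retry
semantics: the extract ID is a SHA-256 content hash of (subject, archetype,
date, payload), so a re-sent extract is recognized downstream. Batch
conversion never aborts: per-record failures (unmapped literals, duplicate
activity days) are collected into a report, matching an unattended daily
send where partial success plus a log is the operational contract.

The XML dialect is this artifact's own, fixed and versioned
(`urn:ontobridge:extract:1`), with a shipped XSD. Byte-stability is a
design goal (dedupe-by-hash, reproducible re-runs): documents are
canonicalized before writing (entries sorted by archetype, date, rc_id,
then a full-content tie-break; elements by node id), encoded UTF-8 with LF
endings, 2-space indent and fixed attribute order, and no timestamp is
injected at write time. Kind-specific attribute rules that XSD 1.0 cannot
express (e.g. `conceptId` only on coded values) are enforced by the parser
after schema validation.

### Ontology repository

The repository is an rdflib graph under a fixed namespace, persisted as
Turtle. The knowledge layer has an `ENTRY` class, one concept class per
archetype as its subclass (e.g. `Secondary_effect`), one property per
element, and a SNOMED CT metaclass: every bound concept is a class typed
(`rdf:type`) as an instance of that metaclass and annotated with
`concept_id` and `code_uri`. Using plain type links rather than true OWL
metaclasses keeps the graph out of OWL-Full reasoning territory while
expressing the same binding pattern.

Ingestion validates the extract, resolves the pseudonymous app subject to
the study identifier through the link table (the only place the two IDs
meet — extracts themselves never carry study or hospital IDs), inserts one
instance per entry, and assigns `rc_id` as a monotonically increasing
integer. Ingestion is idempotent on extract ID: a re-sent extract returns
the original insertion results and changes nothing. Rejection (validation
or linkage) is atomic — the graph is untouched.

Report percentages are rounded half-up to one decimal
(`Decimal.quantize(..., ROUND_HALF_UP)`); the total-users denominator is
passed explicitly because never-users leave no trace in the repository.

### Synthetic cohort generator

The generator emulates a pilot cohort: patients are allocated, some drop
out (with a reason breakdown), some never use the app, and the remaining
users report intermittently. The bundled `STUDY_DEFAULTS` configuration
is 62 allocated, dropouts 7/2/2/1 (total 12), 3 never-users → 47 users;
234 side-effect records over exactly 34 users and 866 activity records
over exactly 38 users, dated within 2020-12-22..2022-04-04.

Counts are allocated **constructively**: totals are partitioned across the
configured number of reporting users (each ≥1, capped at one record per
day) and then assigned to distinct dates, so the configured volumes are
reproduced exactly on every seed rather than in expectation. Randomness
(which users report, which dates, which finding/severity literals, step
counts) comes from a seeded Mersenne Twister (`random.Random`). Dropouts
and never-users generate no records and no link-table rows — the
conservative reading, attributing all extracts to active users, which is
also what makes the per-archetype patient denominators come out of the
configured user count.

What the generator does *not* emulate: symptom trajectories or any
correlation between findings, severities and activity; seasonal or
weekly usage patterns; pre-dropout activity from dropouts; quality-of-life
questionnaires. Passing tests therefore demonstrate the pipeline's
structural and semantic correctness at realistic volumes, not clinical
realism of the content.

## Numerical and degenerate-input choices

- Percentages: half-up, one decimal, `0.0` for a zero denominator.
- Quantity magnitudes serialize as integers when integral, else `repr` of
  the float (exact round-trip).
- Empty mapping sections are legal (warned); an empty archetype registry
  yields an ontology with only the 13606 layer.
- A zero-allocated cohort generates empty outputs; infeasible targets
  (more reporting users than users, fewer records than reporters, more
  activity records than user-days) are rejected before generation.

## Problem sizes

The default end-to-end run (1100 extracts through conversion, XML, and
ingestion into the graph) completes in a few seconds on one CPU; property
tests run with 30 derandomized examples each.

## Known limitations

- One entry per extract; multi-entry extracts are read, validated and
  ingested correctly but never produced by the converter.
- No transport layer (HTTPS, retries) — files and library calls are the
  interface; the repository's ingestion API is a stand-in for a real
  service contract.
- No SNOMED CT release ingestion or subsumption; bindings are flat lookup
  tables.
- Archetype cardinalities beyond required/optional are unsupported.
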