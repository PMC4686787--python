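# Methods

This note records the model the package implements, the choices made where
the design was genuinely open, and what the test material does and does not
demonstrate.

## The workflow dialect

Workflow files use the minimal XPDL 2.x structural skeleton — `Package →
WorkflowProcesses → WorkflowProcess → {Activities, Transitions}` — with all
record-system semantics in `ExtendedAttribute` elements, because that is the
part of XPDL every editor emits and the engine actually needs; layout,
pools, lanes, deadlines and sub-flows are outside the dialect. Attribute
definitions are flat `KEY=value;KEY=value` records (`FLUX_FIELD` on an
activity; `FLUX_REGISTRY` and `FLUX_SUGGEST` at package level). A flat
record is editor-agnostic and bit-exactly specifiable; its one reserved
character is `;`, which serialization therefore rejects inside values.
Unknown keys lint as warnings so files written by richer tools still load.

Parsing and linting are one shared analysis pass, which makes the central
soundness property hold by construction: a document parses if and only if
it has zero error-severity lint issues. Warnings (unreachable activities,
OR-join fan-ins, attribute shadowing, unknown keys) never block loading.

## Attribute kinds and validation

Eight kinds: `integer`, `real`, `text`, `date`, `choice`, `register`,
`table`, `computed`. Numeric bounds are **inclusive** (the natural reading
of a clinical range). Dates are ISO 8601 `YYYY-MM-DD` only; reals accept
`.` as the decimal separator only — both for locale independence and
sortability. Registry matching is exact and case-sensitive: the register
kind exists to *prevent* misspellings, so near-misses (edit distance ≤ 2)
are named in the error message but never silently accepted. An empty string
for a non-required attribute means "absent" and stores no value (absence
must be representable); for a required attribute it is `missing-required`.
Empty table cells likewise store no value for that column. Validation is
total — any finite text input yields a typed value or a complete list of
classified errors, never an exception — and reports all applicable errors,
not the first.

## The formula language

Computed attributes and suggestion conditions share one closed expression
grammar: numbers, identifiers, unary minus, `+ - * /` with standard
precedence and left associativity, parentheses, `years_between(a, b)`, and
comparison operators (`== != < <= > >=`) at lowest precedence. The
comparisons are the one extension beyond plain arithmetic: suggestion
conditions must yield true/false, and a single shared grammar is simpler
and no less safe than two. Computed attributes must still evaluate to a
number; a boolean result is an error. The evaluator is a closed
interpreter over the parse tree — it can perform arithmetic, comparison and
calendar difference and nothing else, which is what makes formulas safe to
accept from workflow files. `years_between` counts completed calendar years
truncated toward zero (the clinical "age" convention; a Feb-29 anniversary
completes on Mar 1). Division by zero, unbound names and type mismatches
are evaluation errors naming the offending symbol, never values.

At execution time a computed attribute is evaluated over the union of the
submission's own values and the latest values of ancestor activities
(those reachable backwards through transitions), with the local activity
shadowing ancestors on a name collision — the least surprising resolution,
flagged by a lint warning at parse time. If an optional input is absent the
derived value is simply absent; an evaluation *error* fails the whole
submission (`formula-error`), because storing a half-derived execution
would violate the no-invalid-persistence guarantee.

## The state machine

Availability is recomputed from the execution set and the transition list
on every query; there is no cached state to corrupt. Joins are OR-joins: an
activity with several incoming transitions becomes available when *any*
predecessor has run. The branching these protocols need models alternative
diagnostic strategies — different clinicians ask different questions — and
an AND-join would deadlock the path not taken. The linter flags multi-
predecessor activities (`or-join` warning) so workflow authors know the
semantics. Re-execution of an executed activity is allowed and versioned
(1, 2, …): both longitudinal re-assessment and correction need it, and an
auditable system must never overwrite history.

## Store, audit, permissions

The store is a single self-contained JSON document (workflows serialized as
XPDL text, live registry state, cases with typed values, users,
permissions, audit log). An embedded single-file store keeps a whole record
system inspectable and snapshot-friendly; the interface is backend-
agnostic. Each audit entry carries a SHA-256 hash chained over its
predecessor, sequence numbers are 1..n with no gaps, and every successful
mutating operation appends exactly one entry. Permission denials are also
audited (`outcome=denied`) — security events deserve accountability —
while failed validations append nothing (nothing changed). Read operations
(status, export, report, audit queries) are not audited so that reads
provably never mutate the store. Execute-activity entries carry the raw
submitted text, which is what makes the log a replayable journal: replay
re-applies every ok-outcome entry through the public operations, including
full validation. Workflow registration is configuration, not a patient-data
mutation, and is not journaled.

Authorization is default-deny over (role, workflow, activity, right)
grants with `*` wildcards; `write` conveys execution, `read` conveys
retrieval and export. Registry appends require workflow-level (wildcard-
activity) write, since a registry belongs to the workflow. Authentication
is identity assertion via `--user`/config — passwords are a deployment
concern outside this package's scope.

Snapshots are zip archives of the store plus a SHA-256 manifest; restore is
all-or-nothing (truncation, digest mismatch or a broken audit chain raises
an integrity error and restores nothing).

## Batch import and export

The batch format is UTF-8 RFC-4180 CSV with header
`case_id,activity,attribute,row_index,column,value`: `row_index` 0 for
scalars, 1..k plus a column name for table cells. Groups — one per
(case, activity) — are independent submissions; one group's failure never
blocks another. The csv-long export adds a `version` column, which the
importer accepts and ignores (version counters restart at 1 on import).
Computed-attribute rows in an imported file are dropped and re-derived.
Referencing a forward case id creates every case up to it, so exports from
stores containing execution-free cases keep their numbering on re-import;
ids below the counter that do not exist are rejected.

Exports default to latest versions (analysis wants current state);
`all_versions` switches to full history (audit wants history). The wide
dialect excludes repeating tables rather than inventing a lossy flattening
— the long dialect carries them faithfully. ARFF declares NUMERIC for
integer/real/computed, `DATE "yyyy-MM-dd"` for dates, nominal enumerations
from the declared choices or the *live* registry entries, STRING otherwise;
missing values are `?` in ARFF and empty cells in wide CSV. One known
representational limit: an execution that stored no values (every attribute
optional and absent) produces no csv-long rows and is therefore invisible
to re-import.

## Synthetic data

The generator exists because real records of the modeled diseases cannot
ship with software; it exercises the *type system and state machine*, not
medicine. Defaults: 2 passes over each case, each available activity
executed with probability 0.8 per pass (enough to produce both complete and
partial trajectories), integers/reals uniform within declared bounds, dates
uniform in 1950–2020, choices and registry entries uniform over their
domains, tables 0–4 rows, text from a fixed word list; optional attributes
are left absent 15% of the time. Availability cascades within a pass (an
execution can unlock its successors immediately), so small pass counts
still reach deep activities. Every stored execution is guaranteed at least
one value (see the representational limit above). With a non-zero
`invalid_fraction`, each generated value flips to a deliberately
out-of-domain one with that probability and the generator asserts the
engine rejects the submission; where a kind admits no invalid value
(optional text), the submission is skipped rather than stored, so
`invalid_fraction=1` provably stores nothing. Everything is a pure function
of the seed; equal specs give byte-identical csv-long exports.

Synthetic cohorts carry no clinical realism: no correlated symptoms, no
plausible trajectories, no reference ranges. Passing tests therefore
demonstrate engine correctness on structurally faithful data, not medical
validity on real data.

Random *workflows* (for the round-trip and state-machine property suites)
have forward-only transition graphs of up to 12 activities, mixed attribute
kinds, occasional registries, computed attributes and suggestion rules;
document order is then a topological order, which mirrors how the packaged
protocols are written.

## Fixture protocols

The packaged `nmo`/`pcm`/`ald` files reproduce the published *structure* of
the three protocols: 16 activities for neuromyelitis optica (including the
auto-identified Identification step, the Date of First Evaluation, and the
flexible Family History table), the SAME hospital identifier and the
35-condition / 29-disease yes/no batteries for paracoccidioidomycosis, and
9 activities with extensible treatment/symptom registries (defaults
Fatigue, Leg Pain) and result-driven suggestions for adrenoleukodystrophy.
Activity names beyond the published ones are reconstructions, and the PCM
battery items are numbered stand-ins (`condition_01`…) — the individual
item names are not published and inventing medical facts would be worse
than a visible placeholder. Each file says so in a leading comment. The
engine is tested against counts and structure, not medical content.

## Problem sizes and numerical choices

The property suites run 500 random workflows for the state-machine
equivalence check, 200 for serialization round trips and 10⁴ fuzz strings
per attribute kind — sizes at which every property has stabilized while the
whole suite stays interactive (a few seconds). The reference synthetic
cohort for the audit/replay properties is 50 cases at seed 7. Floats are
rendered with `repr` (shortest round-tripping form), so text → value →
text is the identity on canonical input and export/import round trips are
byte-exact. Timestamps flow through an injectable clock (`TickClock` in
tests and examples) so reports and stores are reproducible; wall-clock UTC
is the default in production use.

## Known limitations

* Single-writer, desk-scale: operations are atomic per case, but there is
  no concurrent multi-session story and no client/server deployment.
* No free-text NLP, units conversion or reference-range flagging; no PDF
  reports; no live bridges to statistics environments (file export stands
  in) or instruments (the batch path stands in).
* The permission model is role-based allow-lists without authentication.
* Choice/register kinds cannot be table columns (columns carry no nested
  constraint vocabulary).
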