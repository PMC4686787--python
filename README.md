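# fluxcase

Workflow-defined electronic health records for rare and complex diseases.

Rare diseases rarely justify a purpose-built electronic health record (EHR)
system, so their data ends up in rigid generic tools or in free text that
cannot be analyzed. `fluxcase` takes the laboratory-information-management
(LIMS) approach instead: the **entire data model lives in a workflow
definition file** — an XPDL-subset XML document declaring the protocol's
activities (consultations, exams, diagnoses), the transitions between them,
and every typed attribute each activity collects. Supporting a new disease
means writing a new workflow file; the engine never changes.

The package ships three complete protocol definitions as fixtures —
neuromyelitis optica (`@nmo`, 16 activities), paracoccidioidomycosis
(`@pcm`, with batteries of 35 yes/no medical conditions and 29 yes/no
present/previous diseases), and adrenoleukodystrophy (`@ald`, 9 activities)
— plus a seeded generator for synthetic patient cohorts, so everything is
testable without patient data.

## The model

A workflow is a directed graph of activities. For a patient **case**
(identified by an auto-generated number), each activity is in one of three
states, recomputable from the execution history alone:

* **executed** — it has at least one stored execution;
* **available** — not executed, and it has no incoming transition or at
  least one predecessor is executed (an OR-join: branches model
  *alternative* diagnostic strategies, and the clinician chooses);
* **locked** — otherwise.

Each activity carries typed attributes with the kinds `integer`, `real`,
`text`, `date` (ISO 8601), `choice` (closed enumeration), `register` (value
must already exist in a named, optionally extensible lookup table — the
defence against misspelled free text), `table` (a repeating set of scalar
columns, e.g. one row per affected family member), and `computed` (derived
by a formula over other attributes, e.g.
`years_between(first_symptom_date, birth_date)`). Validation is total: raw
text either becomes a typed value or a complete list of structured errors,
and nothing invalid is ever stored. Every mutation appends one entry to a
SHA-256 hash-chained, append-only audit log that doubles as a journal:
replaying it from an empty store reproduces all latest values. Suggestion
rules evaluate conditions over recorded results to propose next activities.
Case data exports to `csv-long` (lossless, re-importable), `csv-wide`, and
ARFF for Weka-style analysis tools.

## Worked example

```python
from fluxcase import engine
from fluxcase.fixtures import load_fixture
from fluxcase.store import Permission, Store, TickClock, User

wf = load_fixture("ald")
store = Store(clock=TickClock())          # deterministic clock
store.add_workflow(wf)
store.add_user(User("dra", "Dr. A", "physician"))
store.grant_permission(Permission("physician", "*", "*",
                                  frozenset({"read", "write"})))

case = engine.create_case(store, wf, user="dra")
engine.execute_activity(
    store, wf, case.case_id, "diagnosis_information",
    {"patient_initials": "J.S.", "birth_date": "1980-06-01",
     "first_symptom_date": "2010-06-01", "vlcfa_c26_umol_l": "2.5"},
    "dra",
)
print(engine.latest_values(case, "diagnosis_information")["age_at_first_symptom"].value)
print(engine.suggest_next(case, wf))
```

prints

```
30
['treatment']
```

`30` is the derived age at first symptom — the workflow's computed attribute
evaluated `years_between` over the two recorded dates. `['treatment']` is
the suggestion rule firing: the recorded C26:0 fatty-acid level (2.5 µmol/L)
exceeds the rule's 1.3 µmol/L threshold, so the protocol proposes the
treatment step next. The scripts in `examples/` walk through parsing and
linting, the full case lifecycle, batch import/export, and synthetic
cohorts with audit verification; each prints the numbers it computes and
what they mean.

The same operations are available from the shell:

```sh
fluxcase lint @nmo
fluxcase new-case @ald --user dra
fluxcase exec @ald 1 diagnosis_information --set patient_initials=J.S. \
    --set birth_date=1980-06-01 --user dra
fluxcase status @ald 1
fluxcase export @ald --dialect arff -o ald.arff
```

Users, roles and the store location come from a YAML config file
(`fluxcase.yaml` in the working directory, `--config`, or
`FLUXCASE_CONFIG`); see `fluxcase --help`.

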