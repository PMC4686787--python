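"""One patient's journey through the adrenoleukodystrophy protocol.

Creates a case, records the diagnosis information (watch the computed
age-at-first-symptom appear), follows a suggestion, and extends a registry —
all against a store with a deterministic clock so the output is stable.
"""

from fluxcase import engine
from fluxcase.fixtures import load_fixture
from fluxcase.store import Permission, Store, TickClock, User

wf = load_fixture("ald")
store = Store(clock=TickClock())
store.add_workflow(wf)
store.add_user(User("dra", "Dr. A", "physician"))
store.grant_permission(
    Permission("physician", "*", "*", frozenset({"read", "write"}))
)

case = engine.create_case(store, wf, user="dra")
print("case id:", case.case_id)  # auto-generated, 1 in an empty store

engine.execute_activity(
    store, wf, case.case_id, "diagnosis_information",
    {
        "patient_initials": "J.S.",
        "birth_date": "1980-06-01",
        "first_symptom_date": "2010-06-01",
        "vlcfa_c26_umol_l": "2.5",
    },
    "dra",
)
values = engine.latest_values(case, "diagnosis_information")
print("age at first symptom (derived):", values["age_at_first_symptom"].value)

# The recorded C26:0 level exceeds the rule threshold (1.3 µmol/L), so the
# workflow's suggestion rule fires for the next available step:
print("suggested next:", engine.suggest_next(case, wf))

# A treatment not in the pre-built list is first registered, then usable:
store.append_registry_entry("ald", "ald_treatments", "Dietary therapy", "dra")
engine.execute_activity(
    store, wf, case.case_id, "treatment", {"treatment": "Dietary therapy"}, "dra"
)
print("treatment recorded:",
      engine.latest_values(case, "treatment")["treatment"].value)

states = {s.activity_id: s.state for s in engine.status(case, wf)}
print("states:", states)
# 'executed' activities have run, 'available' can run now (a predecessor
# ran), 'locked' must wait for their part of the protocol.
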