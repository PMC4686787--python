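"""Case lifecycle, availability state machine, execution and suggestions."""

import random

import pytest

from fluxcase import engine
from fluxcase.errors import (
    ActivityLocked,
    NeverExecuted,
    PermissionDenied,
    UnknownActivity,
    ValidationFailed,
)
from fluxcase.synth import random_workflow
from oracles import state_oracle


def states(case, wf):
    return {s.activity_id: s.state for s in engine.status(case, wf)}


def test_case_ids_start_at_one_and_increase(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    ids = [engine.create_case(admin_store, linear_wf, "doc").case_id for _ in range(3)]
    assert ids == [1, 2, 3]


def test_case_ids_unique_across_interleaved_workflows(admin_store, linear_wf, branch_wf):
    admin_store.add_workflow(linear_wf)
    admin_store.add_workflow(branch_wf)
    a = engine.create_case(admin_store, linear_wf, "doc")
    b = engine.create_case(admin_store, branch_wf, "doc")
    c = engine.create_case(admin_store, linear_wf, "doc")
    assert len({a.case_id, b.case_id, c.case_id}) == 3
    assert c.case_id == 3


def test_linear_availability(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    case = engine.create_case(admin_store, linear_wf, "doc")
    assert states(case, linear_wf) == {"a": "available", "b": "locked", "c": "locked"}
    engine.execute_activity(admin_store, linear_wf, case.case_id, "a", {}, "doc")
    assert states(case, linear_wf) == {"a": "executed", "b": "available", "c": "locked"}


def test_branch_lets_the_user_choose(admin_store, branch_wf):
    """After the fork point both alternatives open up at once."""
    admin_store.add_workflow(branch_wf)
    case = engine.create_case(admin_store, branch_wf, "doc")
    engine.execute_activity(admin_store, branch_wf, case.case_id, "a", {}, "doc")
    assert states(case, branch_wf) == {"a": "executed", "b": "available", "c": "available"}


def test_locked_activity_rejected_and_store_unchanged(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    case = engine.create_case(admin_store, linear_wf, "doc")
    before = len(admin_store.audit)
    with pytest.raises(ActivityLocked):
        engine.execute_activity(admin_store, linear_wf, case.case_id, "c", {}, "doc")
    assert case.executions == []
    assert len(admin_store.audit) == before


def test_unknown_activity(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    case = engine.create_case(admin_store, linear_wf, "doc")
    with pytest.raises(UnknownActivity):
        engine.execute_activity(admin_store, linear_wf, case.case_id, "zz", {}, "doc")


def test_permission_denied_is_audited(admin_store, linear_wf):
    from fluxcase.store import User

    admin_store.add_workflow(linear_wf)
    admin_store.add_user(User("nurse", "N", "nursing"))
    case = engine.create_case(admin_store, linear_wf, "doc")
    with pytest.raises(PermissionDenied):
        engine.execute_activity(admin_store, linear_wf, case.case_id, "a", {}, "nurse")
    denied = [e for e in admin_store.audit if e.outcome == "denied"]
    assert len(denied) == 1 and denied[0].user == "nurse"


def test_validation_failure_stores_nothing(admin_store, typed_wf):
    admin_store.add_workflow(typed_wf)
    case = engine.create_case(admin_store, typed_wf, "doc")
    with pytest.raises(ValidationFailed) as info:
        engine.execute_activity(
            admin_store, typed_wf, case.case_id, "intake",
            {"age": "150", "status": "maybe"}, "doc",
        )
    assert sorted(e.code for e in info.value.errors) == ["not-in-choices", "out-of-range"]
    assert case.executions == []


def test_execution_types_values_and_derives_computed(admin_store, typed_wf):
    admin_store.add_workflow(typed_wf)
    case = engine.create_case(admin_store, typed_wf, "doc")
    execution = engine.execute_activity(
        admin_store, typed_wf, case.case_id, "intake",
        {
            "age": "35",
            "weight": "80",
            "height": "2.0",
            "drug": "Itraconazole",
            "relatives": [{"relative": "mother", "onset_year": "1990"}],
        },
        "doc",
    )
    assert execution.version == 1
    assert execution.values["age"].value == 35
    assert execution.values["bmi"].value == 20.0
    assert execution.values["relatives"].value[0]["onset_year"] == 1990
    assert "visit_date" not in execution.values  # absent optional stays absent


def test_reexecution_versions_and_history_survives(admin_store, typed_wf):
    admin_store.add_workflow(typed_wf)
    case = engine.create_case(admin_store, typed_wf, "doc")
    engine.execute_activity(admin_store, typed_wf, case.case_id, "intake", {"age": "35"}, "doc")
    second = engine.execute_activity(
        admin_store, typed_wf, case.case_id, "intake", {"age": "36"}, "doc"
    )
    assert second.version == 2
    assert engine.latest_values(case, "intake")["age"].value == 36
    versions = [e.version for e in case.executions_of("intake")]
    assert versions == [1, 2]
    assert case.executions_of("intake")[0].values["age"].value == 35


def test_latest_values_requires_an_execution(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    case = engine.create_case(admin_store, linear_wf, "doc")
    with pytest.raises(NeverExecuted):
        engine.latest_values(case, "a")


def test_computed_context_uses_ancestor_values(admin_store, ald_wf):
    """age_at_first_symptom pulls birth_date from the identification step."""
    admin_store.add_workflow(ald_wf)
    case = engine.create_case(admin_store, ald_wf, "doc")
    engine.execute_activity(
        admin_store, ald_wf, case.case_id, "diagnosis_information",
        {
            "patient_initials": "J.S.",
            "birth_date": "1980-06-01",
            "first_symptom_date": "2010-06-01",
        },
        "doc",
    )
    values = engine.latest_values(case, "diagnosis_information")
    assert values["age_at_first_symptom"].value == 30


def test_suggestions_follow_rules_and_availability(admin_store, ald_wf):
    admin_store.add_workflow(ald_wf)
    case = engine.create_case(admin_store, ald_wf, "doc")
    assert engine.suggest_next(case, ald_wf) == []  # nothing executed yet
    engine.execute_activity(
        admin_store, ald_wf, case.case_id, "diagnosis_information",
        {"patient_initials": "J.S.", "birth_date": "1980-06-01",
         "vlcfa_c26_umol_l": "2.5"},
        "doc",
    )
    assert engine.suggest_next(case, ald_wf) == ["treatment"]
    # condition false -> no suggestion
    engine.execute_activity(
        admin_store, ald_wf, case.case_id, "diagnosis_information",
        {"patient_initials": "J.S.", "birth_date": "1980-06-01",
         "vlcfa_c26_umol_l": "0.4"},
        "doc",
    )
    assert engine.suggest_next(case, ald_wf) == []


def test_suggested_but_executed_activities_are_filtered(admin_store, ald_wf):
    admin_store.add_workflow(ald_wf)
    case = engine.create_case(admin_store, ald_wf, "doc")
    engine.execute_activity(
        admin_store, ald_wf, case.case_id, "diagnosis_information",
        {"patient_initials": "J.S.", "birth_date": "1980-06-01",
         "vlcfa_c26_umol_l": "2.5"},
        "doc",
    )
    engine.execute_activity(
        admin_store, ald_wf, case.case_id, "treatment",
        {"treatment": "Lorenzo's oil"}, "doc",
    )
    assert engine.suggest_next(case, ald_wf) == []


def test_executed_set_only_grows(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    case = engine.create_case(admin_store, linear_wf, "doc")
    engine.execute_activity(admin_store, linear_wf, case.case_id, "a", {}, "doc")
    engine.execute_activity(admin_store, linear_wf, case.case_id, "a", {}, "doc")
    assert states(case, linear_wf)["a"] == "executed"


def test_state_machine_matches_brute_force_oracle(admin_store):
    """Random graphs × random execution sequences agree with the oracle."""
    rng = random.Random(77)
    for _ in range(60):
        wf = random_workflow(rng, max_activities=12, with_attributes=False)
        admin_store.add_workflow(wf)
        case = engine.create_case(admin_store, wf, "doc")
        edges = [(t.from_activity, t.to_activity) for t in wf.transitions]
        for _step in range(2 * len(wf.activities)):
            expected = state_oracle(wf.activity_ids, edges, case.executed_ids())
            assert states(case, wf) == expected
            available = [a for a, s in expected.items() if s == "available"]
            if not available:
                break
            engine.execute_activity(
                admin_store, wf, case.case_id, rng.choice(available), {}, "doc"
            )
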