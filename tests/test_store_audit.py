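"""Persistence, registries, permissions, audit chain, snapshot, replay."""

import json
import zipfile

import pytest

from fluxcase import engine
from fluxcase.errors import (
    IntegrityError,
    PermissionDenied,
    RegistryNotExtensible,
    UnknownRegistry,
)
from fluxcase.store import Permission, Store, TickClock, User
from fluxcase.synth import SynthSpec, generate_cases


def test_append_registry_entry_grows_by_one(admin_store, ald_wf):
    admin_store.add_workflow(ald_wf)
    before = admin_store.registries_for("ald")["ald_treatments"].entries
    updated = admin_store.append_registry_entry(
        "ald", "ald_treatments", "Dietary therapy", "doc"
    )
    assert len(updated.entries) == len(before) + 1
    assert updated.entries[-1] == "Dietary therapy"


def test_append_duplicate_is_idempotent_but_audited(admin_store, ald_wf):
    admin_store.add_workflow(ald_wf)
    admin_store.append_registry_entry("ald", "ald_symptoms", "Fatigue", "doc")
    assert admin_store.registries_for("ald")["ald_symptoms"].entries.count("Fatigue") == 1
    entry = admin_store.audit[-1]
    assert entry.action == "append-registry" and entry.detail["noop"] is True


def test_append_to_non_extensible_rejected(admin_store, typed_wf):
    from fluxcase.model import RegistryDef

    closed = typed_wf
    closed.registries["drugs"] = RegistryDef("drugs", ("Itraconazole",), extensible=False)
    admin_store.add_workflow(closed)
    with pytest.raises(RegistryNotExtensible):
        admin_store.append_registry_entry("typed", "drugs", "New drug", "doc")
    with pytest.raises(UnknownRegistry):
        admin_store.append_registry_entry("typed", "ghost", "x", "doc")


def test_appended_entries_are_immediately_valid_input(admin_store, ald_wf):
    admin_store.add_workflow(ald_wf)
    admin_store.append_registry_entry("ald", "ald_symptoms", "Night cramps", "doc")
    case = engine.create_case(admin_store, ald_wf, "doc")
    engine.execute_activity(
        admin_store, ald_wf, case.case_id, "diagnosis_information",
        {"patient_initials": "A.B.", "birth_date": "1990-01-01"}, "doc",
    )
    engine.execute_activity(
        admin_store, ald_wf, case.case_id, "treatment",
        {"treatment": "Lorenzo's oil"}, "doc",
    )
    execution = engine.execute_activity(
        admin_store, ald_wf, case.case_id, "symptoms",
        {"symptom": "Night cramps"}, "doc",
    )
    assert execution.values["symptom"].value == "Night cramps"


# -- permissions -----------------------------------------------------------


def test_default_deny(store, linear_wf):
    assert store.check_permission("anyone", "linear", "a", "read") is False
    assert store.check_permission("anyone", "linear", "a", "write") is False


def test_wildcard_and_specific_grants(store):
    store.add_user(User("w", "W", "wild"))
    store.add_user(User("r", "R", "reader"))
    store.grant_permission(Permission("wild", "nmo", "*", frozenset({"read", "write"})))
    store.grant_permission(Permission("reader", "nmo", "identification", frozenset({"read"})))
    assert store.check_permission("w", "nmo", "anything", "write")
    assert store.check_permission("r", "nmo", "identification", "read")
    assert not store.check_permission("r", "nmo", "identification", "write")
    assert not store.check_permission("r", "nmo", "other", "read")
    assert not store.check_permission("w", "pcm", "identification", "write")


def test_read_only_user_can_retrieve_but_not_execute(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    admin_store.add_user(User("viewer", "V", "viewing"))
    admin_store.grant_permission(Permission("viewing", "*", "*", frozenset({"read"})))
    case = engine.create_case(admin_store, linear_wf, "doc")
    engine.execute_activity(admin_store, linear_wf, case.case_id, "a", {}, "doc")
    with pytest.raises(PermissionDenied):
        engine.execute_activity(admin_store, linear_wf, case.case_id, "b", {}, "viewer")
    assert admin_store.check_permission("viewer", "linear", "a", "read")


# -- audit trail ------------------------------------------------------------


def test_exactly_one_entry_per_successful_mutation(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    base = len(admin_store.audit)
    case = engine.create_case(admin_store, linear_wf, "doc")
    engine.execute_activity(admin_store, linear_wf, case.case_id, "a", {}, "doc")
    engine.execute_activity(admin_store, linear_wf, case.case_id, "b", {}, "doc")
    assert [e.seq for e in admin_store.audit] == list(range(1, base + 4))
    assert [e.action for e in admin_store.audit[base:]] == [
        "create-case", "execute-activity", "execute-activity",
    ]


def test_failed_execution_appends_nothing(admin_store, typed_wf):
    admin_store.add_workflow(typed_wf)
    case = engine.create_case(admin_store, typed_wf, "doc")
    before = len(admin_store.audit)
    with pytest.raises(Exception):
        engine.execute_activity(
            admin_store, typed_wf, case.case_id, "intake", {"age": "bad"}, "doc"
        )
    assert len(admin_store.audit) == before


def test_hash_chain_detects_tampering(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    engine.create_case(admin_store, linear_wf, "doc")
    assert admin_store.verify_chain() is True
    # tamper through serialization, as an attacker editing the file would
    data = admin_store.to_jsonable()
    data["audit"][0]["user"] = "mallory"
    with pytest.raises(IntegrityError):
        Store.from_jsonable(data).verify_chain()


def test_audit_filters_and_ordering(admin_store, linear_wf):
    admin_store.add_workflow(linear_wf)
    admin_store.add_user(User("b", "B", "physician"))
    case = engine.create_case(admin_store, linear_wf, "doc")
    engine.execute_activity(admin_store, linear_wf, case.case_id, "a", {}, "b")
    by_user = admin_store.audit_log(user="b")
    assert [e.user for e in by_user] == ["b"]
    by_case = admin_store.audit_log(case_id=case.case_id)
    assert [e.action for e in by_case] == ["create-case", "execute-activity"]
    assert [e.seq for e in admin_store.audit_log()] == sorted(
        e.seq for e in admin_store.audit_log()
    )


def test_audit_log_requires_read_right(admin_store):
    with pytest.raises(PermissionDenied):
        admin_store.audit_log(requester="stranger")
    assert admin_store.audit_log(requester="doc") is not None


def test_empty_store_has_empty_log(store):
    assert store.audit_log() == []


# -- replay and snapshot -----------------------------------------------------


def _synthetic_store(n_cases=5, seed=7):
    store = Store(clock=TickClock())
    from fluxcase.fixtures import load_fixture

    wf = load_fixture("nmo")
    generate_cases(SynthSpec("nmo", n_cases, seed=seed), wf, store)
    return store, wf


def test_replay_from_empty_reproduces_latest_values():
    store, wf = _synthetic_store()
    replayed = store.replay()
    assert set(replayed.cases) == set(store.cases)
    for case_id, case in store.cases.items():
        twin = replayed.get_case(case_id)
        assert twin.executed_ids() == case.executed_ids()
        for activity_id in case.executed_ids():
            assert dict(engine.latest_values(twin, activity_id)) == dict(
                engine.latest_values(case, activity_id)
            )


def test_snapshot_restore_round_trip(tmp_path):
    store, _ = _synthetic_store()
    archive = tmp_path / "snapshot.zip"
    store.snapshot(archive)
    restored = Store.restore(archive)
    assert restored.to_jsonable() == store.to_jsonable()


def test_snapshot_of_empty_store(tmp_path):
    store = Store(clock=TickClock())
    archive = tmp_path / "empty.zip"
    store.snapshot(archive)
    restored = Store.restore(archive)
    assert restored.cases == {} and restored.audit == []


def test_truncated_archive_is_all_or_nothing(tmp_path):
    store, _ = _synthetic_store(n_cases=2)
    archive = tmp_path / "snapshot.zip"
    store.snapshot(archive)
    blob = archive.read_bytes()
    truncated = tmp_path / "truncated.zip"
    truncated.write_bytes(blob[: len(blob) // 2])
    with pytest.raises(IntegrityError):
        Store.restore(truncated)


def test_tampered_archive_digest_rejected(tmp_path):
    store, _ = _synthetic_store(n_cases=1)
    archive = tmp_path / "snapshot.zip"
    store.snapshot(archive)
    with zipfile.ZipFile(archive) as z:
        payload = json.loads(z.read("store.json"))
        manifest = z.read("integrity.json")
    payload["cases"] = []
    forged = tmp_path / "forged.zip"
    with zipfile.ZipFile(forged, "w") as z:
        z.writestr("store.json", json.dumps(payload))
        z.writestr("integrity.json", manifest)
    with pytest.raises(IntegrityError):
        Store.restore(forged)


def test_save_load_json_round_trip(tmp_path):
    store, _ = _synthetic_store(n_cases=3)
    path = tmp_path / "store.json"
    store.save(path)
    assert Store.load(path).to_jsonable() == store.to_jsonable()
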