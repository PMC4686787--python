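"""Batch file execution, CSV/ARFF export, and the per-case report."""

import pytest

from fluxcase import batch, engine, export
from fluxcase.errors import BatchFormatError
from fluxcase.store import Permission, Store, TickClock, User
from fluxcase.synth import SynthSpec, generate_cases
from oracles import read_arff

HEADER = "case_id,activity,attribute,row_index,column,value\n"


@pytest.fixture
def typed_store(admin_store, typed_wf):
    admin_store.add_workflow(typed_wf)
    return admin_store


def test_two_valid_groups_match_manual_execution(typed_store, typed_wf):
    text = HEADER + (
        "1,intake,age,0,,35\n"
        "1,intake,weight,0,,80\n"
        "2,intake,age,0,,41\n"
    )
    summary = batch.batch_execute(text, typed_wf, typed_store, "doc")
    assert summary.n_executed == 2 and not summary.line_errors
    assert engine.latest_values(typed_store.get_case(1), "intake")["age"].value == 35
    assert engine.latest_values(typed_store.get_case(2), "intake")["age"].value == 41


def test_group_failures_are_independent(typed_store, typed_wf):
    text = HEADER + (
        "1,intake,age,0,,35\n"
        "2,intake,age,0,,999\n"  # out of range: this group only fails
    )
    summary = batch.batch_execute(text, typed_wf, typed_store, "doc")
    outcomes = {(g.case_id, g.ok) for g in summary.groups}
    assert outcomes == {(1, True), (2, False)}
    assert typed_store.get_case(1).executions
    assert not typed_store.get_case(2).executions


def test_empty_file_is_a_clean_no_op(typed_store, typed_wf):
    summary = batch.batch_execute(HEADER, typed_wf, typed_store, "doc")
    assert summary.groups == [] and summary.line_errors == []
    assert summary.n_executed == 0


def test_bad_header_is_fatal(typed_store, typed_wf):
    with pytest.raises(BatchFormatError):
        batch.batch_execute("a,b,c\n1,2,3\n", typed_wf, typed_store, "doc")


def test_malformed_line_skips_its_group_only(typed_store, typed_wf):
    text = HEADER + (
        "1,intake,age,0,,35\n"
        "2,intake,age,zero,,41\n"  # bad row_index
    )
    summary = batch.batch_execute(text, typed_wf, typed_store, "doc")
    assert summary.n_executed == 1
    assert any("line 3" in e for e in summary.line_errors)


def test_table_rows_assemble_in_index_order(typed_store, typed_wf):
    text = HEADER + (
        "1,intake,age,0,,35\n"
        "1,intake,relatives,2,relative,aunt\n"
        "1,intake,relatives,1,relative,mother\n"
        "1,intake,relatives,1,onset_year,1990\n"
    )
    summary = batch.batch_execute(text, typed_wf, typed_store, "doc")
    assert summary.n_executed == 1
    table = engine.latest_values(typed_store.get_case(1), "intake")["relatives"].value
    assert table[0]["relative"] == "mother" and table[1]["relative"] == "aunt"


def test_batch_appends_one_batch_entry_plus_one_per_group(typed_store, typed_wf):
    base = len(typed_store.audit)
    batch.batch_execute(
        HEADER + "1,intake,age,0,,35\n2,intake,age,0,,41\n",
        typed_wf, typed_store, "doc",
    )
    actions = [e.action for e in typed_store.audit[base:]]
    assert actions.count("execute-activity") == 2
    assert actions.count("batch-execute") == 1
    assert actions.count("create-case") == 2  # sequential auto-creation


def test_forward_case_reference_creates_intermediate_cases(typed_store, typed_wf):
    summary = batch.batch_execute(
        HEADER + "3,intake,age,0,,35\n", typed_wf, typed_store, "doc"
    )
    (group,) = summary.groups
    assert group.ok
    assert sorted(typed_store.cases) == [1, 2, 3]  # 1 and 2 exist but are empty
    assert typed_store.get_case(1).executions == []


def test_invalid_case_reference_is_rejected(typed_store, typed_wf):
    summary = batch.batch_execute(
        HEADER + "0,intake,age,0,,35\n", typed_wf, typed_store, "doc"
    )
    (group,) = summary.groups
    assert not group.ok and "unknown case 0" in group.errors[0]


# -- export -----------------------------------------------------------------


def _populated(typed_store, typed_wf):
    case = engine.create_case(typed_store, typed_wf, "doc")
    engine.execute_activity(
        typed_store, typed_wf, case.case_id, "intake",
        {
            "age": "35", "weight": "80", "height": "2.0",
            "status": "present", "drug": "Itraconazole",
            "relatives": [{"relative": "mother", "onset_year": "1990"}],
        },
        "doc",
    )
    return case


def test_csv_long_row_conservation(typed_store, typed_wf):
    """Row count = scalar values (incl. computed) + table cells."""
    _populated(typed_store, typed_wf)
    text = export.csv_long_text(typed_store, typed_wf)
    lines = text.strip().split("\n")
    assert lines[0] == "case_id,activity,version,attribute,row_index,column,value"
    # 5 scalars + 1 computed + 2 table cells
    assert len(lines) - 1 == 8


def test_csv_wide_shape_and_table_exclusion(typed_store, typed_wf):
    _populated(typed_store, typed_wf)
    table = export.export_cases(typed_store, typed_wf, "csv-wide")
    assert table.header[:3] == ("case_id", "activity", "version")
    assert "intake.relatives" not in table.header  # tables excluded from wide
    assert "intake.bmi" in table.header
    assert len(table.rows) == 1  # one (case, activity, latest-version) row


def test_all_versions_export(typed_store, typed_wf):
    case = _populated(typed_store, typed_wf)
    engine.execute_activity(
        typed_store, typed_wf, case.case_id, "intake", {"age": "36"}, "doc"
    )
    latest = export.export_cases(typed_store, typed_wf, "csv-wide")
    full = export.export_cases(typed_store, typed_wf, "csv-wide", all_versions=True)
    assert len(latest.rows) == 1 and len(full.rows) == 2


def test_arff_is_readable_and_nominal_domains_match(typed_store, typed_wf):
    """The declared ARFF schema must agree with the workflow's domains,
    as seen by an independent minimal ARFF reader."""
    _populated(typed_store, typed_wf)
    text = export.render_export(typed_store, typed_wf, "arff")
    relation, attributes, data = read_arff(text)
    assert relation == "typed"
    specs = dict(attributes)
    assert specs["intake.age"] == "NUMERIC"
    assert specs["intake.bmi"] == "NUMERIC"
    assert specs["intake.status"] == ["present", "absent"]
    assert specs["intake.drug"] == ["Itraconazole", "Fluconazole"]
    assert specs["intake.visit_date"].startswith("DATE")
    assert len(data) == 1
    row = dict(zip([n for n, _ in attributes], data[0]))
    assert row["intake.age"] == "35"
    assert row["intake.visit_date"] == "?"  # missing marker


def test_arff_registry_domain_tracks_live_registry(typed_store, typed_wf):
    _populated(typed_store, typed_wf)
    typed_store.append_registry_entry("typed", "drugs", "Voriconazole", "doc")
    _, attributes, _ = read_arff(export.render_export(typed_store, typed_wf, "arff"))
    assert dict(attributes)["intake.drug"][-1] == "Voriconazole"


def test_export_requires_read_on_all_activities(typed_store, typed_wf):
    from fluxcase.errors import PermissionDenied

    _populated(typed_store, typed_wf)
    typed_store.add_user(User("noread", "N", "norole"))
    with pytest.raises(PermissionDenied):
        export.export_cases(typed_store, typed_wf, "csv-long", user="noread")
    export.export_cases(typed_store, typed_wf, "csv-long", user="doc")


def test_export_reimport_round_trip_is_byte_identical():
    store = Store(clock=TickClock())
    from fluxcase.fixtures import load_fixture

    wf = load_fixture("nmo")
    generate_cases(SynthSpec("nmo", 4, seed=11), wf, store)
    first = export.csv_long_text(store, wf)

    fresh = Store(clock=TickClock())
    fresh.add_workflow(wf)
    fresh.add_user(User("synth", "S", "synth"))
    fresh.grant_permission(Permission("synth", "*", "*", frozenset({"read", "write"})))
    summary = batch.batch_execute(first, wf, fresh, "synth")
    assert all(g.ok for g in summary.groups)
    assert export.csv_long_text(fresh, wf) == first


def test_report_fresh_case_is_header_only(typed_store, typed_wf):
    case = engine.create_case(typed_store, typed_wf, "doc")
    report = export.case_report(typed_store, typed_wf, case.case_id)
    assert report.startswith(f"Case {case.case_id}\n")
    assert "==" not in report


def test_report_sections_follow_workflow_order(admin_store, branch_wf):
    admin_store.add_workflow(branch_wf)
    case = engine.create_case(admin_store, branch_wf, "doc")
    engine.execute_activity(admin_store, branch_wf, case.case_id, "a", {}, "doc")
    engine.execute_activity(admin_store, branch_wf, case.case_id, "c", {}, "doc")
    engine.execute_activity(admin_store, branch_wf, case.case_id, "b", {}, "doc")
    report = export.case_report(admin_store, branch_wf, case.case_id)
    positions = [report.index(f"== {name}") for name in ("A", "B", "C")]
    assert positions == sorted(positions)


def test_report_is_deterministic_and_omits_hints(typed_store, typed_wf):
    _populated(typed_store, typed_wf)
    first = export.case_report(typed_store, typed_wf, 1)
    assert first == export.case_report(typed_store, typed_wf, 1)
    assert "hint" not in first.lower()
    assert "mother" in first  # table rows rendered
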