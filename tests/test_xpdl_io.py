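"""Workflow file parsing, serialization and linting."""

import random

import pytest

from fluxcase.errors import WorkflowParseError
from fluxcase.fixtures import FIXTURE_NAMES, fixture_source, load_fixture
from fluxcase.synth import random_workflow
from fluxcase.xpdl_io import lint_workflow, parse_workflow, serialize_workflow

MINIMAL = """<?xml version="1.0"?>
<Package xmlns="http://www.wfmc.org/2008/XPDL2.1" Id="mini" Name="Minimal">
  <WorkflowProcesses>
    <WorkflowProcess Id="mini" Name="Minimal">
      <Activities>
        <Activity Id="only" Name="Only step"/>
      </Activities>
    </WorkflowProcess>
  </WorkflowProcesses>
</Package>
"""


def test_minimal_document_parses():
    wf = parse_workflow(MINIMAL)
    assert len(wf.activities) == 1
    assert wf.transitions == ()
    assert wf.workflow_id == "mini"


def test_parse_decodes_field_records():
    doc = MINIMAL.replace(
        '<Activity Id="only" Name="Only step"/>',
        '<Activity Id="only" Name="Only step">'
        "<ExtendedAttributes>"
        '<ExtendedAttribute Name="FLUX_FIELD" '
        'Value="NAME=age;KIND=integer;REQUIRED=true;MIN=0;MAX=120;'
        'EXAMPLE=35;HINT=age in years"/>'
        "</ExtendedAttributes></Activity>",
    )
    wf = parse_workflow(doc)
    (attr,) = wf.activities[0].attributes
    assert (attr.name, attr.kind, attr.required) == ("age", "integer", True)
    assert (attr.min, attr.max) == (0.0, 120.0)
    assert attr.example == "35" and attr.hint == "age in years"


def test_malformed_xml_reports_line():
    issues = lint_workflow("<Package>\n<broken")
    assert issues[0].severity == "error"
    assert issues[0].code == "malformed-xml"
    assert issues[0].line is not None


def test_unknown_transition_endpoint_is_structured():
    doc = MINIMAL.replace(
        "</Activities>",
        "</Activities><Transitions>"
        '<Transition Id="t1" From="only" To="ghost"/></Transitions>',
    )
    with pytest.raises(WorkflowParseError) as info:
        parse_workflow(doc)
    assert any(
        i.code == "unknown-transition-endpoint" and "ghost" in i.message
        for i in info.value.issues
    )


def test_unknown_kind_is_rejected():
    doc = MINIMAL.replace(
        '<Activity Id="only" Name="Only step"/>',
        '<Activity Id="only" Name="Only step"><ExtendedAttributes>'
        '<ExtendedAttribute Name="FLUX_FIELD" Value="NAME=x;KIND=blob"/>'
        "</ExtendedAttributes></Activity>",
    )
    with pytest.raises(WorkflowParseError) as info:
        parse_workflow(doc)
    assert any(i.code == "unsupported-kind" for i in info.value.issues)


def test_computed_reference_must_resolve():
    doc = MINIMAL.replace(
        '<Activity Id="only" Name="Only step"/>',
        '<Activity Id="only" Name="Only step"><ExtendedAttributes>'
        '<ExtendedAttribute Name="FLUX_FIELD" Value="NAME=y;KIND=computed;FORMULA=ghost + 1"/>'
        "</ExtendedAttributes></Activity>",
    )
    issues = lint_workflow(doc)
    assert any(i.code == "unknown-formula-symbol" for i in issues)
    with pytest.raises(WorkflowParseError):
        parse_workflow(doc)


def test_unreachable_activity_is_a_warning_only():
    doc = MINIMAL.replace(
        "</Activities>",
        '<Activity Id="second" Name="Second"/><Activity Id="island" Name="Island"/>'
        "</Activities><Transitions>"
        '<Transition Id="t1" From="only" To="second"/>'
        '<Transition Id="t2" From="island" To="second"/></Transitions>',
    )
    issues = lint_workflow(doc)
    assert not any(i.severity == "error" for i in issues)
    # 'island' has no incoming edge, so it is itself a start: reachable.
    doc2 = doc.replace(
        '<Transition Id="t2" From="island" To="second"/>',
        '<Transition Id="t2" From="second" To="island"/>',
    )
    assert parse_workflow(doc2).activity("island") is not None


def test_cycle_without_start_is_rejected():
    doc = MINIMAL.replace(
        "</Activities>",
        '<Activity Id="b" Name="B"/></Activities><Transitions>'
        '<Transition Id="t1" From="only" To="b"/>'
        '<Transition Id="t2" From="b" To="only"/></Transitions>',
    )
    issues = lint_workflow(doc)
    assert any(i.code == "no-start-activity" for i in issues)


@pytest.mark.parametrize(
    "mutation, code",
    [
        (('Id="only"', 'Id="only"'), None),  # control: untouched parses
        (('From="only" To="ghost"', None), "unknown-transition-endpoint"),
    ],
)
def test_lint_soundness_on_examples(mutation, code):
    """Documents with zero error-severity issues parse; others raise."""
    doc = MINIMAL
    if code:
        doc = doc.replace(
            "</Activities>",
            "</Activities><Transitions>"
            f'<Transition Id="t1" {mutation[0]}/></Transitions>',
        )
    issues = lint_workflow(doc)
    has_errors = any(i.severity == "error" for i in issues)
    if code is None:
        assert not has_errors
        parse_workflow(doc)
    else:
        assert has_errors
        with pytest.raises(WorkflowParseError):
            parse_workflow(doc)


@pytest.mark.parametrize("name", FIXTURE_NAMES)
def test_fixtures_lint_clean_and_round_trip(name):
    issues = lint_workflow(fixture_source(name))
    assert [i for i in issues if i.severity == "error"] == []
    wf = load_fixture(name)
    assert parse_workflow(serialize_workflow(wf)) == wf


def test_document_order_is_preserved():
    wf = load_fixture("nmo")
    reparsed = parse_workflow(serialize_workflow(wf))
    assert reparsed.activity_ids == wf.activity_ids
    for original, again in zip(wf.activities, reparsed.activities):
        assert again.attribute_names == original.attribute_names


def test_table_column_order_round_trips():
    wf = load_fixture("nmo")
    table = wf.activity("family_history").attributes[0]
    again = parse_workflow(serialize_workflow(wf)).activity("family_history").attributes[0]
    assert again.columns == table.columns
    assert [c for c, _ in table.columns] == ["relative", "condition", "onset_year"]


def test_random_workflows_round_trip():
    """parse∘serialize is the identity on seeded random workflows."""
    rng = random.Random(20240)
    for _ in range(60):
        wf = random_workflow(rng)
        assert parse_workflow(serialize_workflow(wf)) == wf


def test_unknown_record_key_is_warned_not_fatal():
    doc = MINIMAL.replace(
        '<Activity Id="only" Name="Only step"/>',
        '<Activity Id="only" Name="Only step"><ExtendedAttributes>'
        '<ExtendedAttribute Name="FLUX_FIELD" Value="NAME=x;KIND=text;COLOR=red"/>'
        "</ExtendedAttributes></Activity>",
    )
    issues = lint_workflow(doc)
    assert any(i.code == "unknown-field-key" and i.severity == "warning" for i in issues)
    assert parse_workflow(doc).activities[0].attributes[0].name == "x"
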