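"""Case lifecycle: creation, activity availability, execution, suggestions.

The state machine is intentionally simple and fully recomputable from the
execution history:

* an activity is **executed** once it has at least one stored execution;
* it is **available** when not executed and either it has no incoming
  transitions (a start activity) or at least one predecessor is executed
  (an OR-join — branching in these protocols models *alternative* diagnostic
  strategies, so requiring every predecessor would deadlock the untaken
  branch);
* otherwise it is **locked**.

Re-execution of an executed activity is allowed and versioned: clinical
corrections and repeat consultations must never destroy history. Computed
attributes are derived at execution time over the union of the submission's
own values and the latest values of ancestor activities, with the local
activity shadowing ancestors on a name collision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from . import typesystem
from .errors import (
    ActivityLocked,
    EvaluationError,
    NeverExecuted,
    PermissionDenied,
    UnknownActivity,
    UnknownWorkflow,
    ValidationFailed,
)
from .formula import evaluate_formula
from .model import AttributeValue, WorkflowDefinition
from .typesystem import ValidationError

__all__ = [
    "PatientCase",
    "ActivityExecution",
    "ActivityStatus",
    "create_case",
    "status",
    "execute_activity",
    "suggest_next",
    "latest_values",
]


@dataclass(frozen=True)
class ActivityExecution:
    """One validated, versioned submission of an activity's values."""

    activity_id: str
    version: int
    executed_at: str
    executed_by: str
    values: Mapping[str, AttributeValue]


@dataclass
class PatientCase:
    """One patient's instance of a workflow, identified by an auto number."""

    case_id: int
    workflow_id: str
    created_at: str
    executions: list[ActivityExecution] = field(default_factory=list)

    def executed_ids(self) -> set[str]:
        return {e.activity_id for e in self.executions}

    def executions_of(self, activity_id: str) -> list[ActivityExecution]:
        return [e for e in self.executions if e.activity_id == activity_id]


@dataclass(frozen=True)
class ActivityStatus:
    activity_id: str
    state: str  # "executed" | "available" | "locked"


def create_case(store, wf: WorkflowDefinition, user: str) -> PatientCase:
    """Create a fresh case; the numeric id is 1 + the highest existing id."""
    if not store.has_workflow(wf.workflow_id):
        raise UnknownWorkflow(f"workflow {wf.workflow_id!r} is not loaded in the store")
    return store.create_case(wf.workflow_id, user)


def status(case: PatientCase, wf: WorkflowDefinition) -> list[ActivityStatus]:
    """One status per activity, in workflow order."""
    executed = case.executed_ids()
    result = []
    for act in wf.activities:
        if act.activity_id in executed:
            state = "executed"
        else:
            preds = wf.predecessors(act.activity_id)
            state = "available" if not preds or preds & executed else "locked"
        result.append(ActivityStatus(activity_id=act.activity_id, state=state))
    return result


def latest_values(
    case: PatientCase, activity_id: str
) -> Mapping[str, AttributeValue]:
    """Values of the highest-version execution of ``activity_id``."""
    executions = case.executions_of(activity_id)
    if not executions:
        raise NeverExecuted(
            f"activity {activity_id!r} has never been executed for case {case.case_id}"
        )
    return max(executions, key=lambda e: e.version).values


def _computed_context(
    case: PatientCase, wf: WorkflowDefinition, activity_id: str, own: dict
) -> dict:
    context: dict = {}
    executed = case.executed_ids()
    for ancestor in wf.ancestors(activity_id):
        if ancestor in executed:
            context.update(latest_values(case, ancestor))
    context.update(own)  # the local activity shadows ancestors
    return context


def execute_activity(
    store,
    wf: WorkflowDefinition,
    case_id: int,
    activity_id: str,
    raw_values: Mapping[str, object],
    user: str,
) -> ActivityExecution:
    """Validate and store one activity submission.

    On any validation error nothing is stored and :class:`ValidationFailed`
    carries the complete error collection. A successful call appends one
    execution (version incremented on re-execution) and exactly one audit
    entry. Permission denials are themselves audited.
    """
    case = store.get_case(case_id)
    activity = wf.activity(activity_id)
    if activity is None:
        raise UnknownActivity(
            f"workflow {wf.workflow_id!r} has no activity {activity_id!r}"
        )
    if not store.check_permission(user, wf.workflow_id, activity_id, "write"):
        store.audit_denied(
            user,
            "execute-activity",
            f"case:{case_id}/activity:{activity_id}",
            {"case_id": case_id, "activity_id": activity_id},
        )
        raise PermissionDenied(
            f"user {user!r} may not execute {activity_id!r} on {wf.workflow_id!r}"
        )
    state = {s.activity_id: s.state for s in status(case, wf)}[activity_id]
    if state == "locked":
        raise ActivityLocked(
            f"activity {activity_id!r} is locked for case {case_id}"
        )

    registries = store.registries_for(wf.workflow_id)
    errors: list[ValidationError] = []
    values: dict[str, AttributeValue] = {}
    known = {a.name: a for a in activity.attributes}
    for name in raw_values:
        attr = known.get(name)
        if attr is None or attr.kind == "computed":
            errors.append(
                ValidationError(
                    name,
                    "unknown-attribute",
                    f"{name!r} is not a user-supplied attribute of {activity_id!r}",
                )
            )
    for attr in activity.attributes:
        if attr.kind == "computed":
            continue
        outcome = typesystem.validate_value(
            attr, raw_values.get(attr.name), registries
        )
        if isinstance(outcome, list):
            errors.extend(outcome)
        elif outcome is not None:
            values[attr.name] = outcome

    context = _computed_context(case, wf, activity_id, values)
    for attr in activity.attributes:
        if attr.kind != "computed" or attr.formula is None:
            continue
        if not attr.formula.referenced_names <= set(context):
            continue  # an optional input is absent; the derived value is too
        try:
            derived = evaluate_formula(attr.formula, context)
        except EvaluationError as exc:
            errors.append(
                ValidationError(attr.name, "formula-error", str(exc))
            )
            continue
        if isinstance(derived, bool):
            errors.append(
                ValidationError(
                    attr.name,
                    "formula-error",
                    "computed attributes must evaluate to a number",
                )
            )
            continue
        values[attr.name] = AttributeValue(
            attribute=attr.name, kind="computed", value=derived
        )

    if errors:
        raise ValidationFailed(activity_id, errors)

    previous = case.executions_of(activity_id)
    version = 1 + max((e.version for e in previous), default=0)
    execution = ActivityExecution(
        activity_id=activity_id,
        version=version,
        executed_at=store.now(),
        executed_by=user,
        values=values,
    )
    store.add_execution(case_id, execution, user, raw_values)
    return execution


def suggest_next(case: PatientCase, wf: WorkflowDefinition) -> list[str]:
    """Follow-up activities suggested by the workflow's rules.

    Evaluates every rule whose source activity is executed against that
    activity's latest values; concatenates the suggestions of rules whose
    condition holds, de-duplicated in first-occurrence order and filtered to
    currently available activities. Rules whose condition fails to evaluate
    are skipped.
    """
    executed = case.executed_ids()
    available = {s.activity_id for s in status(case, wf) if s.state == "available"}
    suggested: list[str] = []
    for rule in wf.suggestion_rules:
        if rule.source_activity not in executed:
            continue
        context = latest_values(case, rule.source_activity)
        try:
            outcome = evaluate_formula(rule.condition, context)
        except EvaluationError as exc:
            logging.getLogger(__name__).warning(
                "suggestion rule %s skipped: %s", rule.rule_id, exc
            )
            continue
        truthy = outcome is True or (
            not isinstance(outcome, bool)
            and isinstance(outcome, (int, float))
            and outcome != 0
        )
        if truthy:
            for target in rule.suggested_activities:
                if target in available and target not in suggested:
                    suggested.append(target)
    return suggested
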