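"""In-memory model of a workflow-defined clinical protocol.

A :class:`WorkflowDefinition` is the single source of truth for one
electronic-health-record protocol: which steps (activities) exist, which
order the transitions allow, which typed fields each step collects, which
lookup registries constrain register-kind fields, and which rules suggest
follow-up steps. All structures are immutable value objects; equality is
structural, which is what the parse/serialize round-trip guarantees are
stated over.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping

from .formula import Formula

__all__ = [
    "SCALAR_KINDS",
    "KINDS",
    "AttributeDef",
    "AttributeValue",
    "ActivityDef",
    "Transition",
    "RegistryDef",
    "SuggestionRule",
    "WorkflowDefinition",
    "encode_attribute_value",
    "decode_attribute_value",
    "payload_to_text",
]

#: Kinds that can appear as table columns and as CSV cells.
SCALAR_KINDS = ("integer", "real", "text", "date", "choice", "register")

#: All attribute kinds.
KINDS = SCALAR_KINDS + ("table", "computed")


@dataclass(frozen=True)
class AttributeDef:
    """One typed field of an activity.

    ``min``/``max`` bound integer and real kinds (inclusive); ``choices``
    enumerates the domain of a choice kind; ``registry`` names the lookup
    table of a register kind; ``columns`` gives (name, scalar kind) pairs for
    a repeating table; ``formula`` derives a computed kind. ``example`` and
    ``hint`` are operator-facing documentation carried by the workflow.
    """

    name: str
    kind: str
    required: bool = False
    min: float | None = None
    max: float | None = None
    choices: tuple[str, ...] = ()
    registry: str | None = None
    columns: tuple[tuple[str, str], ...] = ()
    formula: Formula | None = None
    example: str | None = None
    hint: str | None = None


@dataclass(frozen=True)
class ActivityDef:
    """One protocol step (consultation, exam, diagnosis) with its fields."""

    activity_id: str
    name: str
    attributes: tuple[AttributeDef, ...] = ()

    def attribute(self, name: str) -> AttributeDef | None:
        for attr in self.attributes:
            if attr.name == name:
                return attr
        return None

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)


@dataclass(frozen=True)
class Transition:
    """Directed edge allowing ``to_activity`` once ``from_activity`` ran."""

    from_activity: str
    to_activity: str


@dataclass(frozen=True)
class RegistryDef:
    """A named lookup table for register-kind attributes.

    Extensible registries accept appends at run time (a newly used treatment
    can become a pre-built one); non-extensible registries are closed.
    """

    registry_name: str
    entries: tuple[str, ...] = ()
    extensible: bool = False


@dataclass(frozen=True)
class SuggestionRule:
    """Suggest follow-up activities from the results of an executed one."""

    rule_id: str
    source_activity: str
    condition: Formula
    suggested_activities: tuple[str, ...] = ()


@dataclass(frozen=True)
class WorkflowDefinition:
    workflow_id: str
    name: str
    version: str = "1.0"
    activities: tuple[ActivityDef, ...] = ()
    transitions: tuple[Transition, ...] = ()
    registries: Mapping[str, RegistryDef] = field(default_factory=dict)
    suggestion_rules: tuple[SuggestionRule, ...] = ()

    def activity(self, activity_id: str) -> ActivityDef | None:
        for act in self.activities:
            if act.activity_id == activity_id:
                return act
        return None

    @property
    def activity_ids(self) -> tuple[str, ...]:
        return tuple(a.activity_id for a in self.activities)

    def predecessors(self, activity_id: str) -> set[str]:
        return {
            t.from_activity
            for t in self.transitions
            if t.to_activity == activity_id
        }

    def successors(self, activity_id: str) -> set[str]:
        return {
            t.to_activity
            for t in self.transitions
            if t.from_activity == activity_id
        }

    def start_activities(self) -> tuple[str, ...]:
        targets = {t.to_activity for t in self.transitions}
        return tuple(a for a in self.activity_ids if a not in targets)

    def ancestors(self, activity_id: str) -> tuple[str, ...]:
        """Activities reachable by walking transitions backwards.

        Returned in workflow (document) order, excluding ``activity_id``
        itself; this is the resolution order for computed-attribute contexts.
        """
        seen: set[str] = set()
        frontier = [activity_id]
        while frontier:
            current = frontier.pop()
            for pred in self.predecessors(current):
                if pred not in seen and pred != activity_id:
                    seen.add(pred)
                    frontier.append(pred)
        return tuple(a for a in self.activity_ids if a in seen)


@dataclass(frozen=True)
class AttributeValue:
    """A validated, typed payload for one attribute.

    ``value`` holds an ``int``, ``float``, ``str`` or :class:`datetime.date`
    for scalar kinds, and for tables a tuple of rows, each a mapping of
    column name → scalar payload. Computed attributes store their evaluated
    number under kind ``computed``.
    """

    attribute: str
    kind: str
    value: object


def payload_to_text(value: object) -> str:
    """Canonical text form of a scalar payload (used by CSV/ARFF/report)."""
    if isinstance(value, bool):  # defensive: booleans never stored
        return "true" if value else "false"
    if isinstance(value, datetime.date):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _encode_scalar(value: object) -> object:
    if isinstance(value, datetime.date):
        return {"__date__": value.isoformat()}
    return value


def _decode_scalar(value: object) -> object:
    if isinstance(value, dict) and "__date__" in value:
        return datetime.date.fromisoformat(value["__date__"])
    return value


def encode_attribute_value(av: AttributeValue) -> dict:
    """JSON-safe encoding; inverse of :func:`decode_attribute_value`."""
    if av.kind == "table":
        payload: object = [
            {col: _encode_scalar(cell) for col, cell in row.items()}
            for row in av.value  # type: ignore[union-attr]
        ]
    else:
        payload = _encode_scalar(av.value)
    return {"attribute": av.attribute, "kind": av.kind, "value": payload}


def decode_attribute_value(data: Mapping) -> AttributeValue:
    kind = data["kind"]
    raw = data["value"]
    if kind == "table":
        value: object = tuple(
            {col: _decode_scalar(cell) for col, cell in row.items()} for row in raw
        )
    else:
        value = _decode_scalar(raw)
    return AttributeValue(attribute=data["attribute"], kind=kind, value=value)


def values_equal(
    a: Mapping[str, AttributeValue], b: Mapping[str, AttributeValue]
) -> bool:
    """Structural equality of two value mappings (used by replay checks)."""
    return dict(a) == dict(b)
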