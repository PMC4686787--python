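"""Seeded synthetic workflows and patient cases.

Real records from the modeled diseases cannot ship with a software package,
so everything downstream of the parser is exercised with synthetic material:

* :func:`random_workflow` draws structurally valid workflow definitions —
  forward-edged activity graphs with mixed attribute kinds, registries and
  suggestion rules — used by the round-trip and state-machine property
  suites;
* :func:`generate_cases` populates a store with reproducible patient cases
  for a given workflow, drawing raw values per kind and optionally
  injecting deliberately invalid values to exercise the rejection path.

Synthetic values exercise the *type system*, not medicine: integers and
reals are uniform within declared bounds, dates uniform in 1950–2020,
choices and registry entries uniform over their domains, tables carry 0–4
rows, text comes from a fixed word list. Everything is reproducible from the
seed; two runs from an equal spec produce byte-identical csv-long exports.
"""

from __future__ import annotations

import datetime
import random
from dataclasses import dataclass

from . import engine
from .errors import ValidationFailed
from .formula import parse_formula
from .model import (
    ActivityDef,
    AttributeDef,
    RegistryDef,
    SuggestionRule,
    Transition,
    WorkflowDefinition,
)
from .store import Permission, User

__all__ = ["SynthSpec", "generate_cases", "random_workflow"]

_WORDS = (
    "amber", "basalt", "cedar", "delta", "ember", "fjord",
    "garnet", "harbor", "indigo", "juniper", "krill", "lumen",
)

_DATE_START = datetime.date(1950, 1, 1)
_DATE_END = datetime.date(2020, 12, 31)


@dataclass(frozen=True)
class SynthSpec:
    """Conditions for one synthetic cohort.

    ``completion`` is the probability that each available activity is
    executed on each pass; ``invalid_fraction`` the probability that a
    generated raw value is deliberately out-of-domain (the generator then
    asserts the engine rejects the submission).
    """

    workflow_id: str
    n_cases: int
    seed: int
    completion: float = 0.8
    passes: int = 2
    invalid_fraction: float = 0.0

    def __post_init__(self):
        for name in ("completion", "invalid_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {value}")


# -- random workflow definitions ------------------------------------------


def random_workflow(
    rng: random.Random,
    max_activities: int = 12,
    with_attributes: bool = True,
) -> WorkflowDefinition:
    """Draw a structurally valid workflow definition.

    The transition graph only has forward edges in document order, so the
    document order is also a topological order; the first activity is never
    a transition target, guaranteeing a start activity exists.
    """
    n = rng.randint(1, max_activities)
    registries: dict[str, RegistryDef] = {}
    activities: list[ActivityDef] = []
    for i in range(n):
        attrs: list[AttributeDef] = []
        if with_attributes:
            numeric_names: list[str] = []
            for j in range(rng.randint(0, 3)):
                name = f"a{i}_{j}"
                kind = rng.choice(
                    ["integer", "real", "text", "date", "choice", "table"]
                )
                if kind == "integer":
                    low = rng.randint(-50, 10)
                    attrs.append(
                        AttributeDef(name, "integer", required=rng.random() < 0.3,
                                     min=float(low), max=float(low + rng.randint(1, 200)))
                    )
                    numeric_names.append(name)
                elif kind == "real":
                    low = round(rng.uniform(-10, 10), 1)
                    attrs.append(
                        AttributeDef(name, "real", min=low, max=low + rng.randint(1, 50))
                    )
                    numeric_names.append(name)
                elif kind == "date":
                    attrs.append(AttributeDef(name, "date"))
                elif kind == "choice":
                    domain = tuple(rng.sample(_WORDS, rng.randint(2, 4)))
                    attrs.append(AttributeDef(name, "choice", choices=domain))
                elif kind == "table":
                    cols = tuple(
                        (f"c{k}", rng.choice(["integer", "real", "text", "date"]))
                        for k in range(rng.randint(1, 3))
                    )
                    attrs.append(AttributeDef(name, "table", columns=cols))
                else:
                    attrs.append(
                        AttributeDef(name, "text", required=rng.random() < 0.2,
                                     example="example text" if rng.random() < 0.3 else None,
                                     hint="free text" if rng.random() < 0.3 else None)
                    )
            if rng.random() < 0.25:
                reg_name = f"reg{i}"
                entries = tuple(rng.sample(_WORDS, rng.randint(2, 5)))
                registries[reg_name] = RegistryDef(
                    reg_name, entries, extensible=rng.random() < 0.5
                )
                attrs.append(AttributeDef(f"a{i}_reg", "register", registry=reg_name))
            if numeric_names and rng.random() < 0.4:
                source = rng.choice(numeric_names)
                attrs.append(
                    AttributeDef(
                        f"a{i}_calc",
                        "computed",
                        formula=parse_formula(f"{source} * 2 + 1"),
                    )
                )
        activities.append(
            ActivityDef(activity_id=f"act{i:02d}", name=f"Activity {i}", attributes=tuple(attrs))
        )

    transitions: list[Transition] = []
    for i in range(n):
        for j in range(i + 1, n):
            if j == 0:
                continue
            if rng.random() < (0.6 if j == i + 1 else 0.12):
                transitions.append(
                    Transition(activities[i].activity_id, activities[j].activity_id)
                )

    rules: list[SuggestionRule] = []
    if n >= 2 and rng.random() < 0.3:
        for i, act in enumerate(activities[:-1]):
            numeric = [
                a.name for a in act.attributes if a.kind in ("integer", "real")
            ]
            if numeric:
                target = activities[rng.randrange(i + 1, n)].activity_id
                rules.append(
                    SuggestionRule(
                        rule_id=f"r{i}",
                        source_activity=act.activity_id,
                        condition=parse_formula(f"{rng.choice(numeric)} > 0"),
                        suggested_activities=(target,),
                    )
                )
                break

    return WorkflowDefinition(
        workflow_id=f"wf{rng.randrange(10**6)}",
        name="Synthetic workflow",
        version="1.0",
        activities=tuple(activities),
        transitions=tuple(transitions),
        registries=registries,
        suggestion_rules=tuple(rules),
    )


# -- raw value generation ---------------------------------------------------


def _random_date(rng: random.Random) -> str:
    span = (_DATE_END - _DATE_START).days
    return (_DATE_START + datetime.timedelta(days=rng.randint(0, span))).isoformat()


def _valid_scalar(kind: str, rng, minimum, maximum, choices, registry) -> str:
    if kind == "integer":
        low = int(minimum) if minimum is not None else 0
        high = int(maximum) if maximum is not None else 100
        return str(rng.randint(low, high))
    if kind == "real":
        low = minimum if minimum is not None else 0.0
        high = maximum if maximum is not None else 100.0
        return f"{rng.uniform(low, high):.2f}"
    if kind == "date":
        return _random_date(rng)
    if kind == "choice":
        return rng.choice(choices)
    if kind == "register":
        return rng.choice(registry.entries)
    return " ".join(rng.sample(_WORDS, rng.randint(1, 3)))


def _valid_raw(attr: AttributeDef, rng, registries, non_empty: bool = False):
    if attr.kind == "table":
        rows = []
        for _ in range(rng.randint(1 if (attr.required or non_empty) else 0, 4)):
            rows.append(
                {
                    name: _valid_scalar(kind, rng, None, None, (), None)
                    for name, kind in attr.columns
                }
            )
        return rows
    registry = registries.get(attr.registry) if attr.registry else None
    return _valid_scalar(attr.kind, rng, attr.min, attr.max, attr.choices, registry)


def _invalid_raw(attr: AttributeDef, rng):
    """An out-of-domain raw value, or None when the kind admits none."""
    if attr.kind == "integer":
        if attr.max is not None:
            return str(int(attr.max) + 1 + rng.randint(0, 9))
        return "not-an-integer"
    if attr.kind == "real":
        return "12,5" if rng.random() < 0.5 else "abc"
    if attr.kind == "date":
        return rng.choice(["31/12/1999", "2001-13-40", "yesterday"])
    if attr.kind == "choice":
        return "__not_a_choice__"
    if attr.kind == "register":
        return "__unregistered__"
    if attr.kind == "table":
        bad_cols = {name: "##bad##" for name, kind in attr.columns if kind != "text"}
        if not bad_cols:  # all-text tables admit no invalid cell
            return None
        return [bad_cols]
    if attr.required:  # text: only required-ness is violable
        return ""
    return None


# -- cohort generation ------------------------------------------------------


def generate_cases(spec: SynthSpec, wf: WorkflowDefinition, store, user: str = "synth"):
    """Populate ``store`` with ``spec.n_cases`` reproducible cases of ``wf``.

    Ensures the workflow and a wildcard-write synthetic user exist in the
    store, then makes ``spec.passes`` passes over every case, executing each
    available activity with probability ``spec.completion``. With a non-zero
    ``invalid_fraction``, submissions containing an injected invalid value
    are asserted to be rejected; submissions for which no invalid value
    could be constructed are skipped rather than stored. Returns the created
    cases.
    """
    if spec.workflow_id != wf.workflow_id:
        raise ValueError(
            f"spec is for workflow {spec.workflow_id!r}, got {wf.workflow_id!r}"
        )
    rng = random.Random(spec.seed)
    if not store.has_workflow(wf.workflow_id):
        store.add_workflow(wf)
    if user not in store.users:
        store.add_user(User(user_id=user, name="Synthetic operator", role="synth"))
        store.grant_permission(
            Permission(
                role="synth",
                workflow_id="*",
                activity_id="*",
                rights=frozenset(("read", "write")),
            )
        )
    registries = store.registries_for(wf.workflow_id)

    cases = [engine.create_case(store, wf, user) for _ in range(spec.n_cases)]
    for _ in range(spec.passes):
        for case in cases:
            states = {s.activity_id: s.state for s in engine.status(case, wf)}
            for act in wf.activities:
                if states.get(act.activity_id) != "available":
                    continue
                if rng.random() >= spec.completion:
                    continue
                raw: dict[str, object] = {}
                requested = effective = 0
                for attr in act.attributes:
                    if attr.kind == "computed":
                        continue
                    if not attr.required and rng.random() < 0.15:
                        continue  # leave some optional attributes absent
                    if rng.random() < spec.invalid_fraction:
                        requested += 1
                        bad = _invalid_raw(attr, rng)
                        if bad is None:
                            raw[attr.name] = _valid_raw(attr, rng, registries)
                        else:
                            effective += 1
                            raw[attr.name] = bad
                    else:
                        raw[attr.name] = _valid_raw(attr, rng, registries)
                if spec.invalid_fraction > 0 and effective == 0 and (
                    requested > 0 or not raw
                ):
                    continue  # nothing invalidatable: skip rather than store
                if effective == 0:
                    # Guarantee every stored execution carries at least one
                    # value: the long export has no way to represent a
                    # value-less execution, and round-trippable cohorts are
                    # what this generator is for.
                    if not any(v != [] and v != "" for v in raw.values()):
                        first = next(
                            (a for a in act.attributes if a.kind != "computed"),
                            None,
                        )
                        if first is not None:
                            raw[first.name] = _valid_raw(
                                first, rng, registries, non_empty=True
                            )
                try:
                    engine.execute_activity(
                        store, wf, case.case_id, act.activity_id, raw, user
                    )
                except ValidationFailed:
                    if effective == 0:  # pragma: no cover - generator defect
                        raise
                else:
                    if effective > 0:  # pragma: no cover - engine defect
                        raise AssertionError(
                            "engine accepted a deliberately invalid submission"
                        )
                    states[act.activity_id] = "executed"
                    for successor in wf.successors(act.activity_id):
                        if states.get(successor) == "locked":
                            states[successor] = "available"
    return cases
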