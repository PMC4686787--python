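import pytest

from fluxcase.fixtures import load_fixture
from fluxcase.model import (
    ActivityDef,
    AttributeDef,
    Transition,
    WorkflowDefinition,
)
from fluxcase.store import Permission, Store, TickClock, User


@pytest.fixture
def clock():
    return TickClock()


@pytest.fixture
def store(clock):
    return Store(clock=clock)


@pytest.fixture
def admin_store(store):
    """A store with one wildcard read+write user ('doc', role physician)."""
    store.add_user(User(user_id="doc", name="Dr. A", role="physician"))
    store.grant_permission(
        Permission(
            role="physician",
            workflow_id="*",
            activity_id="*",
            rights=frozenset({"read", "write"}),
        )
    )
    return store


def bare_workflow(workflow_id, activity_ids, edges):
    """A workflow with no attributes — pure state-machine material."""
    return WorkflowDefinition(
        workflow_id=workflow_id,
        name=workflow_id,
        activities=tuple(ActivityDef(a, a.title()) for a in activity_ids),
        transitions=tuple(Transition(f, t) for f, t in edges),
    )


@pytest.fixture
def linear_wf():
    return bare_workflow("linear", ["a", "b", "c"], [("a", "b"), ("b", "c")])


@pytest.fixture
def branch_wf():
    return bare_workflow("branch", ["a", "b", "c"], [("a", "b"), ("a", "c")])


@pytest.fixture
def typed_wf():
    """One-start workflow exercising every user-facing attribute kind."""
    from fluxcase.formula import parse_formula
    from fluxcase.model import RegistryDef

    return WorkflowDefinition(
        workflow_id="typed",
        name="Typed",
        activities=(
            ActivityDef(
                "intake",
                "Intake",
                (
                    AttributeDef("age", "integer", required=True, min=0, max=120),
                    AttributeDef("weight", "real", min=0, max=500),
                    AttributeDef("height", "real", min=0, max=3),
                    AttributeDef("visit_date", "date"),
                    AttributeDef("status", "choice", choices=("present", "absent")),
                    AttributeDef("drug", "register", registry="drugs"),
                    AttributeDef(
                        "relatives",
                        "table",
                        columns=(("relative", "text"), ("onset_year", "integer")),
                    ),
                    AttributeDef(
                        "bmi",
                        "computed",
                        formula=parse_formula("weight / (height * height)"),
                    ),
                ),
            ),
        ),
        registries={
            "drugs": RegistryDef(
                "drugs", entries=("Itraconazole", "Fluconazole"), extensible=True
            )
        },
    )


@pytest.fixture(scope="session")
def nmo_wf():
    return load_fixture("nmo")


@pytest.fixture(scope="session")
def pcm_wf():
    return load_fixture("pcm")


@pytest.fixture(scope="session")
def ald_wf():
    return load_fixture("ald")
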