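"""Packaged disease-protocol workflows and their structural expectations.

Three protocols ship with the package as ``.xpdl`` documents: ``nmo``
(neuromyelitis optica, 16 activities), ``pcm`` (paracoccidioidomycosis,
with 35 yes/no condition and 29 yes/no disease-history attributes in the
First Consultation) and ``ald`` (adrenoleukodystrophy, 9 activities with
extensible registries and suggestion rules). Anywhere the CLI accepts a
workflow file, ``@name`` addresses a fixture.

The files are generated from the builders in ``_protocols`` (regenerate
with ``python -m fluxcase.fixtures.regenerate``); :func:`build_fixtures`
parses them and cross-checks the structural counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from ..model import WorkflowDefinition
from ..xpdl_io import parse_workflow

__all__ = [
    "FIXTURE_NAMES",
    "EXPECTED_COUNTS",
    "FixtureCatalog",
    "fixture_source",
    "load_fixture",
    "build_fixtures",
    "count_yes_no_attributes",
]

FIXTURE_NAMES = ("nmo", "pcm", "ald")

#: Published structural counts each fixture must reproduce.
EXPECTED_COUNTS: dict[str, dict[str, int]] = {
    "nmo": {"activities": 16},
    "pcm": {
        "activities": 6,
        "condition_attributes": 35,
        "disease_history_attributes": 29,
    },
    "ald": {"activities": 9, "registries": 2},
}


@dataclass(frozen=True)
class FixtureCatalog:
    """Parsed fixtures plus the structural counts they were checked against."""

    entries: dict[str, WorkflowDefinition]
    expected_counts: dict[str, dict[str, int]]


def fixture_source(name: str) -> str:
    """The raw XPDL text of a packaged fixture."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; have {FIXTURE_NAMES}")
    return (
        resources.files(__package__).joinpath(f"{name}.xpdl").read_text("utf-8")
    )


def load_fixture(name: str) -> WorkflowDefinition:
    return parse_workflow(fixture_source(name))


def count_yes_no_attributes(wf: WorkflowDefinition, activity_id: str, prefix: str) -> int:
    """Count yes/no choice attributes named ``prefix``* in one activity."""
    activity = wf.activity(activity_id)
    if activity is None:
        return 0
    return sum(
        1
        for attr in activity.attributes
        if attr.name.startswith(prefix)
        and attr.kind == "choice"
        and set(attr.choices) == {"yes", "no"}
    )


def _measured_counts(name: str, wf: WorkflowDefinition) -> dict[str, int]:
    counts = {"activities": len(wf.activities)}
    if name == "pcm":
        counts["condition_attributes"] = count_yes_no_attributes(
            wf, "first_consultation", "condition_"
        )
        counts["disease_history_attributes"] = count_yes_no_attributes(
            wf, "first_consultation", "disease_"
        )
    if name == "ald":
        counts["registries"] = len(wf.registries)
    return counts


def build_fixtures() -> FixtureCatalog:
    """Parse every packaged fixture and verify its structural counts."""
    entries: dict[str, WorkflowDefinition] = {}
    for name in FIXTURE_NAMES:
        wf = load_fixture(name)
        measured = _measured_counts(name, wf)
        if measured != EXPECTED_COUNTS[name]:
            raise AssertionError(
                f"fixture {name!r} drifted: expected {EXPECTED_COUNTS[name]}, "
                f"measured {measured}"
            )
        entries[name] = wf
    return FixtureCatalog(entries=entries, expected_counts=dict(EXPECTED_COUNTS))
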