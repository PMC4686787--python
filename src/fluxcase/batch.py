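"""Batch activity execution from a delimited value file.

The batch path is how instrument output and bulk historical data enter the
record system without typing into forms: a UTF-8 CSV with header
``case_id,activity,attribute,row_index,column,value`` (RFC-4180 quoting),
one row per scalar value (``row_index`` 0, empty ``column``) or table cell
(``row_index`` 1..k plus a column name). Rows are grouped by
``(case_id, activity)``; each group is one submission through the engine,
and groups are independent — one group's validation failure never blocks
the others.

A case id that does not exist yet is auto-created when (and only when) it is
the next id the store would generate, so a csv-long export re-imports into a
fresh store reproducing the same case numbering.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

from . import engine
from .errors import BatchFormatError, FluxcaseError
from .model import WorkflowDefinition

__all__ = ["BATCH_HEADER", "BatchRow", "GroupResult", "BatchSummary", "batch_execute"]

BATCH_HEADER = ["case_id", "activity", "attribute", "row_index", "column", "value"]


@dataclass(frozen=True)
class BatchRow:
    line_no: int
    case_id: int
    activity_id: str
    attribute: str
    row_index: int
    column: str
    value: str


@dataclass
class GroupResult:
    case_id: int
    activity_id: str
    ok: bool
    version: int | None = None
    errors: list[str] = field(default_factory=list)


@dataclass
class BatchSummary:
    """Outcome of one batch run: per-group results plus per-line rejects."""

    groups: list[GroupResult] = field(default_factory=list)
    line_errors: list[str] = field(default_factory=list)

    @property
    def n_executed(self) -> int:
        return sum(1 for g in self.groups if g.ok)

    @property
    def n_failed(self) -> int:
        return sum(1 for g in self.groups if not g.ok) + (
            1 if self.line_errors and not self.groups else 0
        )


def _read_rows(text: str):
    """Parse the CSV into BatchRows; returns (rows, line_errors, poisoned).

    ``poisoned`` holds group keys whose rows were malformed; those groups are
    skipped entirely rather than half-submitted.
    """
    reader = csv.reader(io.StringIO(text, newline=""))
    try:
        header = next(reader)
    except StopIteration:
        raise BatchFormatError("batch file is empty (no header)")
    # A csv-long export carries an extra `version` column; re-imports restart
    # version counters at 1, so that column is accepted and ignored.
    version_at = None
    if header == BATCH_HEADER:
        pass
    elif header == BATCH_HEADER[:2] + ["version"] + BATCH_HEADER[2:]:
        version_at = 2
    else:
        raise BatchFormatError(
            f"batch header must be {','.join(BATCH_HEADER)!r}, got {','.join(header)!r}"
        )
    rows: list[BatchRow] = []
    line_errors: list[str] = []
    poisoned: set[tuple[int, str]] = set()
    for line_no, record in enumerate(reader, start=2):
        if not record or all(cell == "" for cell in record):
            continue
        expected = len(BATCH_HEADER) + (1 if version_at is not None else 0)
        if len(record) != expected:
            line_errors.append(
                f"line {line_no}: expected {expected} cells, got {len(record)}"
            )
            continue
        if version_at is not None:
            record = record[:version_at] + record[version_at + 1 :]
        case_text, activity_id, attribute, index_text, column, value = record
        try:
            case_id = int(case_text)
            row_index = int(index_text)
        except ValueError:
            line_errors.append(f"line {line_no}: case_id and row_index must be integers")
            continue
        if row_index < 0:
            line_errors.append(f"line {line_no}: row_index must be >= 0")
            poisoned.add((case_id, activity_id))
            continue
        rows.append(
            BatchRow(line_no, case_id, activity_id, attribute, row_index, column, value)
        )
    return rows, line_errors, poisoned


def _assemble_group(rows: list[BatchRow]):
    """Turn one group's rows into raw_values for the engine."""
    raw: dict[str, object] = {}
    problems: list[str] = []
    scalar_seen: set[str] = set()
    table_rows: dict[str, dict[int, dict[str, str]]] = {}
    for row in rows:
        if row.row_index == 0:
            if row.column:
                problems.append(
                    f"line {row.line_no}: scalar row must leave column empty"
                )
                continue
            if row.attribute in scalar_seen:
                problems.append(
                    f"line {row.line_no}: duplicate value for {row.attribute!r}"
                )
                continue
            if row.attribute in table_rows:
                problems.append(
                    f"line {row.line_no}: {row.attribute!r} mixes scalar and table rows"
                )
                continue
            scalar_seen.add(row.attribute)
            raw[row.attribute] = row.value
        else:
            if not row.column:
                problems.append(
                    f"line {row.line_no}: table row needs a column name"
                )
                continue
            if row.attribute in scalar_seen:
                problems.append(
                    f"line {row.line_no}: {row.attribute!r} mixes scalar and table rows"
                )
                continue
            cells = table_rows.setdefault(row.attribute, {}).setdefault(
                row.row_index, {}
            )
            if row.column in cells:
                problems.append(
                    f"line {row.line_no}: duplicate cell {row.attribute}[{row.row_index}].{row.column}"
                )
                continue
            cells[row.column] = row.value
    for attribute, indexed in table_rows.items():
        raw[attribute] = [indexed[i] for i in sorted(indexed)]
    return raw, problems


def batch_execute(source, wf: WorkflowDefinition, store, user: str) -> BatchSummary:
    """Execute a batch file against ``wf``.

    ``source`` is a path or CSV text. Each successful group appends one
    execute-activity audit entry (via the engine) and the run appends one
    batch-level entry. Raises :class:`BatchFormatError` only for an unusable
    file (missing/size-mismatched header); everything else is reported in
    the summary.
    """
    if isinstance(source, (str, Path)) and (
        isinstance(source, Path) or "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)

    rows, line_errors, poisoned = _read_rows(text)
    summary = BatchSummary(line_errors=line_errors)

    order: list[tuple[int, str]] = []
    grouped: dict[tuple[int, str], list[BatchRow]] = {}
    for row in rows:
        key = (row.case_id, row.activity_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(row)

    for key in order:
        case_id, activity_id = key
        result = GroupResult(case_id=case_id, activity_id=activity_id, ok=False)
        summary.groups.append(result)
        if key in poisoned:
            result.errors.append("group skipped: malformed rows")
            continue
        raw, problems = _assemble_group(grouped[key])
        if problems:
            result.errors.extend(problems)
            continue
        activity = wf.activity(activity_id)
        if activity is not None:
            # Exports include derived values; on import they are re-derived,
            # never submitted, so computed-attribute rows are dropped here.
            for attr in activity.attributes:
                if attr.kind == "computed":
                    raw.pop(attr.name, None)
        if case_id not in store.cases:
            # Case ids are auto-generated and contiguous from 1; referencing a
            # forward id creates every case up to it (exports from stores with
            # execution-free cases keep their numbering on re-import).
            if case_id >= store.next_case_id() and store.has_workflow(wf.workflow_id):
                while store.next_case_id() <= case_id:
                    store.create_case(wf.workflow_id, user)
            else:
                result.errors.append(f"unknown case {case_id}")
                continue
        try:
            execution = engine.execute_activity(
                store, wf, case_id, activity_id, raw, user
            )
        except FluxcaseError as exc:
            result.errors.append(str(exc))
            continue
        result.ok = True
        result.version = execution.version

    store.record_batch(
        user,
        {
            "workflow_id": wf.workflow_id,
            "groups": len(summary.groups),
            "executed": summary.n_executed,
            "failed": sum(1 for g in summary.groups if not g.ok),
            "line_errors": len(summary.line_errors),
        },
    )
    return summary
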