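"""Export of case data to analysis-ready tables and per-case reports.

Three dialects connect the record store to statistics environments:

* ``csv-long`` — one row per stored scalar value or table cell, columns
  ``case_id,activity,version,attribute,row_index,column,value``. Lossless
  (tables included) and re-importable through the batch path.
* ``csv-wide`` — one row per (case, activity, version), one column per
  scalar attribute under its activity-qualified name ``activity.attribute``.
  Repeating tables are excluded (any flattening would be lossy) with a
  logged notice.
* ``arff`` — the wide table in ARFF form for Weka-style consumers: NUMERIC
  for integer/real/computed, DATE for dates, nominal enumerations for
  choice/register domains, STRING otherwise; missing values as ``?``.

By default only the latest version of each executed activity is exported
(analysis wants current state); ``all_versions=True`` switches to full
history (audit wants history). Exports are reads: they never mutate the
store.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from pathlib import Path

from .engine import PatientCase
from .errors import PermissionDenied, UnknownCase
from .model import (
    ActivityDef,
    AttributeDef,
    WorkflowDefinition,
    payload_to_text,
)

__all__ = ["ExportTable", "export_cases", "csv_long_text", "case_report"]

logger = logging.getLogger(__name__)

LONG_HEADER = ["case_id", "activity", "version", "attribute", "row_index", "column", "value"]

_DIALECTS = ("csv-long", "csv-wide", "arff")


@dataclass(frozen=True)
class ExportTable:
    """A rendered export: header, rows of text cells, and the dialect used."""

    header: tuple[str, ...]
    rows: tuple[tuple[str, ...], ...]
    dialect: str


def _check_read(store, wf: WorkflowDefinition, user: str | None) -> None:
    if user is None:
        return
    for act in wf.activities:
        if not store.check_permission(user, wf.workflow_id, act.activity_id, "read"):
            raise PermissionDenied(
                f"user {user!r} may not read activity {act.activity_id!r}"
            )


def _case_executions(case: PatientCase, wf: WorkflowDefinition, all_versions: bool):
    """Yield executions of one case in workflow order, versions ascending."""
    for act in wf.activities:
        executions = sorted(
            case.executions_of(act.activity_id), key=lambda e: e.version
        )
        if not executions:
            continue
        if not all_versions:
            executions = executions[-1:]
        for execution in executions:
            yield act, execution


def _long_rows(store, wf: WorkflowDefinition, all_versions: bool):
    for _, case in sorted(store.cases.items()):
        if case.workflow_id != wf.workflow_id:
            continue
        for act, execution in _case_executions(case, wf, all_versions):
            for attr in act.attributes:
                value = execution.values.get(attr.name)
                if value is None:
                    continue
                base = (str(case.case_id), act.activity_id, str(execution.version))
                if attr.kind == "table":
                    for index, row in enumerate(value.value, start=1):
                        for col_name, _ in attr.columns:
                            if col_name not in row:
                                continue
                            yield base + (
                                attr.name,
                                str(index),
                                col_name,
                                payload_to_text(row[col_name]),
                            )
                else:
                    yield base + (attr.name, "0", "", payload_to_text(value.value))


def _wide_columns(wf: WorkflowDefinition) -> list[tuple[ActivityDef, AttributeDef]]:
    columns = []
    for act in wf.activities:
        for attr in act.attributes:
            if attr.kind == "table":
                logger.info(
                    "wide export: table attribute %s.%s excluded",
                    act.activity_id,
                    attr.name,
                )
                continue
            columns.append((act, attr))
    return columns


def _wide_rows(store, wf: WorkflowDefinition, all_versions: bool, missing: str):
    columns = _wide_columns(wf)
    header = ["case_id", "activity", "version"] + [
        f"{act.activity_id}.{attr.name}" for act, attr in columns
    ]
    rows = []
    for _, case in sorted(store.cases.items()):
        if case.workflow_id != wf.workflow_id:
            continue
        for act, execution in _case_executions(case, wf, all_versions):
            cells = [str(case.case_id), act.activity_id, str(execution.version)]
            for col_act, attr in columns:
                if col_act.activity_id != act.activity_id:
                    cells.append(missing)
                    continue
                value = execution.values.get(attr.name)
                cells.append(missing if value is None else payload_to_text(value.value))
            rows.append(tuple(cells))
    return tuple(header), tuple(rows)


def _write_csv(header, rows) -> str:
    buffer = io.StringIO(newline="")
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(header)
    writer.writerows(rows)
    return buffer.getvalue()


def _arff_quote(token: str) -> str:
    if token == "" or any(c in token for c in " ,{}%'\"\t"):
        return "'" + token.replace("\\", "\\\\").replace("'", "\\'") + "'"
    return token


def _arff_text(store, wf: WorkflowDefinition, all_versions: bool) -> str:
    header, rows = _wide_rows(store, wf, all_versions, missing="?")
    registries = store.registries_for(wf.workflow_id)
    columns = _wide_columns(wf)
    lines = [f"@RELATION {_arff_quote(wf.workflow_id)}", ""]

    def nominal(values) -> str:
        return "{" + ",".join(_arff_quote(v) for v in values) + "}"

    lines.append("@ATTRIBUTE case_id NUMERIC")
    lines.append(f"@ATTRIBUTE activity {nominal(wf.activity_ids)}")
    lines.append("@ATTRIBUTE version NUMERIC")
    for act, attr in columns:
        name = _arff_quote(f"{act.activity_id}.{attr.name}")
        if attr.kind in ("integer", "real", "computed"):
            spec = "NUMERIC"
        elif attr.kind == "date":
            spec = 'DATE "yyyy-MM-dd"'
        elif attr.kind == "choice":
            spec = nominal(attr.choices)
        elif attr.kind == "register":
            registry = registries.get(attr.registry or "")
            spec = nominal(registry.entries if registry else ())
        else:
            spec = "STRING"
        lines.append(f"@ATTRIBUTE {name} {spec}")
    lines.append("")
    lines.append("@DATA")
    for row in rows:
        lines.append(",".join(c if c == "?" else _arff_quote(c) for c in row))
    return "\n".join(lines) + "\n"


def csv_long_text(store, wf: WorkflowDefinition, all_versions: bool = False) -> str:
    """The csv-long dialect as a string (the round-trippable form)."""
    return _write_csv(LONG_HEADER, list(_long_rows(store, wf, all_versions)))


def export_cases(
    store,
    wf: WorkflowDefinition,
    dialect: str,
    destination=None,
    user: str | None = None,
    all_versions: bool = False,
) -> ExportTable:
    """Render all of ``wf``'s cases in ``dialect``; optionally write a file.

    ``user=None`` means a trusted in-process caller; a named user must hold
    read rights on every exported activity.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}, got {dialect!r}")
    _check_read(store, wf, user)
    if dialect == "csv-long":
        rows = tuple(_long_rows(store, wf, all_versions))
        table = ExportTable(tuple(LONG_HEADER), rows, dialect)
        text = _write_csv(table.header, table.rows)
    elif dialect == "csv-wide":
        header, rows = _wide_rows(store, wf, all_versions, missing="")
        table = ExportTable(header, rows, dialect)
        text = _write_csv(header, rows)
    else:
        header, rows = _wide_rows(store, wf, all_versions, missing="?")
        table = ExportTable(header, rows, dialect)
        text = _arff_text(store, wf, all_versions)
    if destination is not None:
        Path(destination).write_text(text, encoding="utf-8")
    return table


def render_export(store, wf: WorkflowDefinition, dialect: str, all_versions=False) -> str:
    """The export as text without touching the filesystem."""
    if dialect == "csv-long":
        return csv_long_text(store, wf, all_versions)
    if dialect == "csv-wide":
        header, rows = _wide_rows(store, wf, all_versions, missing="")
        return _write_csv(header, rows)
    if dialect == "arff":
        return _arff_text(store, wf, all_versions)
    raise ValueError(f"unknown dialect {dialect!r}")


def case_report(store, wf: WorkflowDefinition, case_id: int) -> str:
    """Deterministic plain-text summary of one case.

    Case header, then one section per *executed* activity in workflow order
    showing the latest values; attribute hints are never printed; tables are
    rendered as aligned rows.
    """
    if case_id not in store.cases:
        raise UnknownCase(f"no case with id {case_id}")
    case = store.cases[case_id]
    lines = [
        f"Case {case.case_id}",
        f"Workflow: {wf.name} ({wf.workflow_id})",
        f"Created: {case.created_at}",
    ]
    for act, execution in _case_executions(case, wf, all_versions=False):
        lines.append("")
        lines.append(
            f"== {act.name} (version {execution.version}, "
            f"by {execution.executed_by} at {execution.executed_at}) =="
        )
        for attr in act.attributes:
            value = execution.values.get(attr.name)
            if value is None:
                continue
            if attr.kind == "table":
                lines.append(f"  {attr.name}:")
                col_names = [c for c, _ in attr.columns]
                grid = [col_names] + [
                    [payload_to_text(row.get(c, "")) for c in col_names]
                    for row in value.value
                ]
                widths = [
                    max(len(r[i]) for r in grid) for i in range(len(col_names))
                ]
                for r in grid:
                    lines.append(
                        "    "
                        + " | ".join(cell.ljust(w) for cell, w in zip(r, widths))
                    )
            else:
                lines.append(f"  {attr.name}: {payload_to_text(value.value)}")
    return "\n".join(lines) + "\n"
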