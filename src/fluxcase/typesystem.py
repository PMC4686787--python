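"""Validation of raw user input against typed attribute definitions.

The whole point of a workflow-defined record system is that data arrives as
*text* — form fields, batch-file cells — and leaves as typed, constrained
values that downstream analysis can trust. :func:`validate_value` is the
single gate: it is total (any finite text input yields either a typed
:class:`~fluxcase.model.AttributeValue` or a list of
:class:`ValidationError` values, never an exception), it reports *all*
applicable failures rather than the first, and it is deterministic.

Conventions fixed here:

* dates are ISO 8601 ``YYYY-MM-DD`` only;
* real numbers use ``.`` as the decimal separator, no grouping;
* numeric bounds are inclusive;
* registry matching is exact and case-sensitive — near misses (edit
  distance ≤ 2) are *mentioned* in the error message but never accepted,
  because the register kind exists precisely to stop misspellings;
* an empty string for a non-required attribute means "absent" (returned as
  ``None``); for a required attribute it is a ``missing-required`` error.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model import AttributeDef, AttributeValue, RegistryDef

__all__ = ["ValidationError", "validate_value"]

_INT_RE = re.compile(r"^[+-]?\d+$")
_REAL_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


@dataclass(frozen=True)
class ValidationError:
    """One classified validation failure.

    ``code`` is one of: missing-required, type-mismatch, out-of-range,
    not-in-choices, not-in-registry, bad-date, bad-table-row,
    unknown-attribute, formula-error. ``row_index`` is set (1-based) for
    table-row failures only.
    """

    attribute: str
    code: str
    message: str
    row_index: int | None = None


def _levenshtein(a: str, b: str, limit: int = 3) -> int:
    """Edit distance with early exit; only small distances matter here."""
    if abs(len(a) - len(b)) > limit:
        return limit + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        if min(cur) > limit:
            return limit + 1
        prev = cur
    return prev[-1]


def _near_misses(value: str, entries: Sequence[str]) -> list[str]:
    return [e for e in entries if 0 < _levenshtein(value, e, 2) <= 2]


def _parse_scalar(
    name: str,
    kind: str,
    raw: str,
    *,
    minimum: float | None = None,
    maximum: float | None = None,
    choices: Sequence[str] = (),
    registry: RegistryDef | None = None,
    registry_name: str | None = None,
):
    """Validate one scalar text value. Returns (payload, errors)."""
    errors: list[ValidationError] = []
    if kind == "integer":
        if not _INT_RE.match(raw):
            return None, [
                ValidationError(name, "type-mismatch", f"{raw!r} is not an integer")
            ]
        value: object = int(raw)
    elif kind == "real":
        if not _REAL_RE.match(raw):
            return None, [
                ValidationError(name, "type-mismatch", f"{raw!r} is not a real number")
            ]
        value = float(raw)
    elif kind == "date":
        if not _DATE_RE.match(raw):
            return None, [
                ValidationError(
                    name, "bad-date", f"{raw!r} is not an ISO date (YYYY-MM-DD)"
                )
            ]
        try:
            value = datetime.date.fromisoformat(raw)
        except ValueError:
            return None, [
                ValidationError(name, "bad-date", f"{raw!r} is not a valid calendar date")
            ]
    elif kind == "choice":
        if raw not in choices:
            domain = ", ".join(choices)
            return None, [
                ValidationError(
                    name, "not-in-choices", f"{raw!r} is not one of: {domain}"
                )
            ]
        value = raw
    elif kind == "register":
        if registry is None:
            return None, [
                ValidationError(
                    name,
                    "not-in-registry",
                    f"registry {registry_name!r} is not loaded",
                )
            ]
        if raw not in registry.entries:
            msg = f"{raw!r} is not registered in {registry.registry_name!r}"
            close = _near_misses(raw, registry.entries)
            if close:
                msg += " (did you mean: " + ", ".join(close) + "?)"
            return None, [ValidationError(name, "not-in-registry", msg)]
        value = raw
    elif kind == "text":
        value = raw
    else:  # pragma: no cover - guarded by lint
        return None, [ValidationError(name, "type-mismatch", f"unknown kind {kind!r}")]

    if kind in ("integer", "real"):
        num = value  # type: ignore[assignment]
        if minimum is not None and num < minimum:  # type: ignore[operator]
            errors.append(
                ValidationError(
                    name, "out-of-range", f"{raw} is below the minimum {minimum:g}"
                )
            )
        if maximum is not None and num > maximum:  # type: ignore[operator]
            errors.append(
                ValidationError(
                    name, "out-of-range", f"{raw} is above the maximum {maximum:g}"
                )
            )
    if errors:
        return None, errors
    return value, []


def _validate_table(
    attr: AttributeDef,
    raw: object,
    registries: Mapping[str, RegistryDef],
):
    if isinstance(raw, (str, bytes)) or not isinstance(raw, Sequence):
        return None, [
            ValidationError(
                attr.name,
                "type-mismatch",
                "table attribute expects a sequence of rows",
            )
        ]
    declared = {name for name, _ in attr.columns}
    rows: list[dict] = []
    errors: list[ValidationError] = []
    for index, row in enumerate(raw, start=1):
        if not isinstance(row, Mapping):
            errors.append(
                ValidationError(
                    attr.name,
                    "bad-table-row",
                    f"row {index} is not a column mapping",
                    row_index=index,
                )
            )
            continue
        for key in row:
            if key not in declared:
                errors.append(
                    ValidationError(
                        attr.name,
                        "bad-table-row",
                        f"row {index} has unknown column {key!r}",
                        row_index=index,
                    )
                )
        typed: dict = {}
        for col_name, col_kind in attr.columns:
            cell = row.get(col_name, "")
            if isinstance(cell, str) and cell.strip() == "":
                continue  # absent cell: no value stored for this column
            if not isinstance(cell, str):
                errors.append(
                    ValidationError(
                        attr.name,
                        "bad-table-row",
                        f"row {index}, column {col_name!r}: cell is not text",
                        row_index=index,
                    )
                )
                continue
            value, cell_errors = _parse_scalar(attr.name, col_kind, cell)
            if cell_errors:
                for err in cell_errors:
                    errors.append(
                        ValidationError(
                            attr.name,
                            "bad-table-row",
                            f"row {index}, column {col_name!r}: {err.message}",
                            row_index=index,
                        )
                    )
            else:
                typed[col_name] = value
        rows.append(typed)
    if errors:
        return None, errors
    return tuple(rows), []


def validate_value(
    attr: AttributeDef,
    raw: object,
    registries: Mapping[str, RegistryDef] | None = None,
) -> AttributeValue | None | list[ValidationError]:
    """Validate raw input for one attribute.

    ``raw`` is text for scalar kinds, or a sequence of column-name → text
    mappings for table kinds. Returns a typed
    :class:`~fluxcase.model.AttributeValue` on success, ``None`` when an
    optional attribute is absent (empty input), or the complete list of
    :class:`ValidationError` values on failure. Never raises on user input;
    computed attributes are derived, not validated, so passing one is a
    programming error.
    """
    if attr.kind == "computed":
        raise TypeError("computed attributes are derived, not validated")
    registries = registries or {}

    absent = raw is None or (isinstance(raw, str) and raw.strip() == "")
    if attr.kind == "table" and isinstance(raw, Sequence) and not isinstance(
        raw, (str, bytes)
    ):
        absent = len(raw) == 0
    if absent:
        if attr.required:
            return [
                ValidationError(
                    attr.name, "missing-required", "required attribute is missing"
                )
            ]
        return None

    if attr.kind == "table":
        value, errors = _validate_table(attr, raw, registries)
    else:
        if not isinstance(raw, str):
            return [
                ValidationError(
                    attr.name,
                    "type-mismatch",
                    f"{attr.kind} attribute expects text input",
                )
            ]
        value, errors = _parse_scalar(
            attr.name,
            attr.kind,
            raw.strip(),
            minimum=attr.min,
            maximum=attr.max,
            choices=attr.choices,
            registry=registries.get(attr.registry) if attr.registry else None,
            registry_name=attr.registry,
        )
    if errors:
        return errors
    return AttributeValue(attribute=attr.name, kind=attr.kind, value=value)
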