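"""Exception hierarchy shared across the package.

Every error a caller can reasonably handle derives from :class:`FluxcaseError`,
so the CLI can map the whole family onto exit code 1. User-input problems in
attribute values are *not* exceptions — they are returned as
:class:`fluxcase.typesystem.ValidationError` data — with one exception:
submitting an activity with invalid values raises :class:`ValidationFailed`,
which carries the full error collection.
"""

from __future__ import annotations


class FluxcaseError(Exception):
    """Base class for all package-level errors."""


class WorkflowParseError(FluxcaseError):
    """A workflow document violates the dialect or a structural invariant.

    Carries the full list of lint issues that caused the rejection.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        errors = [i for i in self.issues if i.severity == "error"]
        head = errors[0] if errors else (self.issues[0] if self.issues else None)
        msg = "workflow rejected"
        if head is not None:
            msg = f"workflow rejected: {head.code} at {head.location}: {head.message}"
            if len(errors) > 1:
                msg += f" (+{len(errors) - 1} more)"
        super().__init__(msg)


class FormulaSyntaxError(FluxcaseError):
    """Formula text does not conform to the expression grammar."""

    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (at offset {offset})")


class EvaluationError(FluxcaseError):
    """Formula evaluation failed (unbound name, bad operand, zero division)."""

    def __init__(self, code: str, symbol: str, message: str | None = None):
        self.code = code
        self.symbol = symbol
        super().__init__(message or f"{code}: {symbol}")


class UnknownWorkflow(FluxcaseError):
    pass


class UnknownCase(FluxcaseError):
    pass


class UnknownActivity(FluxcaseError):
    pass


class ActivityLocked(FluxcaseError):
    pass


class NeverExecuted(FluxcaseError):
    pass


class ValidationFailed(FluxcaseError):
    """Activity submission rejected; nothing was stored.

    ``errors`` is the complete collection of
    :class:`~fluxcase.typesystem.ValidationError` values for the submission.
    """

    def __init__(self, activity_id: str, errors):
        self.activity_id = activity_id
        self.errors = list(errors)
        detail = "; ".join(f"{e.attribute}: {e.code}" for e in self.errors)
        super().__init__(f"validation failed for activity {activity_id!r}: {detail}")


class PermissionDenied(FluxcaseError):
    pass


class UnknownRegistry(FluxcaseError):
    pass


class RegistryNotExtensible(FluxcaseError):
    pass


class IntegrityError(FluxcaseError):
    """A snapshot archive or audit chain failed verification; nothing restored."""


class BatchFormatError(FluxcaseError):
    """The batch file is unreadable or its header does not match the contract."""
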