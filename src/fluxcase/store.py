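"""Persistence, audit trail, users and role-based permissions.

The store is a single self-contained object holding workflows, live registry
state, patient cases and the audit log, serializable to one JSON file. The
embedded single-file design keeps a whole record system inspectable with a
text editor and trivially snapshottable, while the interface stays
backend-agnostic.

The audit log is append-only and tamper-evident: each entry carries a
SHA-256 hash chained over its predecessor, sequence numbers are 1..n with no
gaps, and every successful mutating operation appends exactly one entry
(permission denials are audited too, with ``outcome="denied"`` — security
events deserve accountability). The log doubles as a journal: replaying the
ok-outcome entries from an empty store reproduces every latest value.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

from .errors import (
    IntegrityError,
    PermissionDenied,
    RegistryNotExtensible,
    UnknownCase,
    UnknownRegistry,
    UnknownWorkflow,
)
from .engine import ActivityExecution, PatientCase
from .model import (
    RegistryDef,
    WorkflowDefinition,
    decode_attribute_value,
    encode_attribute_value,
)

__all__ = [
    "User",
    "Permission",
    "AuditEntry",
    "Store",
    "TickClock",
    "READ",
    "WRITE",
    "AUDIT_ACTIONS",
]

READ = "read"
WRITE = "write"

#: Vocabulary of auditable actions. ``export`` is reserved: read-only
#: operations are deliberately not audited so that reads never mutate the
#: store, but the token stays part of the contract for external consumers.
AUDIT_ACTIONS = (
    "create-case",
    "execute-activity",
    "append-registry",
    "create-user",
    "grant-permission",
    "export",
    "batch-execute",
)

_STORE_FORMAT = "fluxcase-store-v1"


@dataclass(frozen=True)
class User:
    user_id: str
    name: str
    role: str


@dataclass(frozen=True)
class Permission:
    """Grant of rights to a role on a workflow's activities.

    ``activity_id`` may be the wildcard ``"*"``. ``write`` conveys the
    ability to execute activities; ``read`` the ability to retrieve values.
    """

    role: str
    workflow_id: str
    activity_id: str
    rights: frozenset[str]


@dataclass(frozen=True)
class AuditEntry:
    seq: int
    timestamp: str
    user: str
    action: str
    subject: str
    outcome: str  # "ok" | "denied"
    detail: dict
    prev_hash: str
    hash: str


class TickClock:
    """Deterministic clock: a fixed start advanced by a fixed step per call."""

    def __init__(
        self,
        start: datetime.datetime | None = None,
        step_seconds: int = 60,
    ):
        self.current = start or datetime.datetime(
            2024, 1, 1, tzinfo=datetime.timezone.utc
        )
        self.step = datetime.timedelta(seconds=step_seconds)

    def __call__(self) -> datetime.datetime:
        value = self.current
        self.current = self.current + self.step
        return value


def _utc_now() -> datetime.datetime:
    return datetime.datetime.now(datetime.timezone.utc)


def _entry_hash(prev_hash: str, core: dict) -> str:
    canonical = json.dumps(core, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256((prev_hash + "|" + canonical).encode("utf-8")).hexdigest()


class Store:
    """In-memory record store with JSON persistence and audit journal."""

    def __init__(self, clock=None):
        self.clock = clock or _utc_now
        self.workflows: dict[str, WorkflowDefinition] = {}
        self.registries: dict[str, dict[str, RegistryDef]] = {}
        self.cases: dict[int, PatientCase] = {}
        self.audit: list[AuditEntry] = []
        self.users: dict[str, User] = {}
        self.permissions: list[Permission] = []

    # -- time -------------------------------------------------------------

    def now(self) -> str:
        return self.clock().isoformat()

    # -- audit ------------------------------------------------------------

    def _append_audit(
        self, user: str, action: str, subject: str, detail: dict, outcome: str = "ok"
    ) -> AuditEntry:
        seq = len(self.audit) + 1
        timestamp = self.now()
        prev_hash = self.audit[-1].hash if self.audit else ""
        core = {
            "seq": seq,
            "timestamp": timestamp,
            "user": user,
            "action": action,
            "subject": subject,
            "outcome": outcome,
            "detail": detail,
        }
        entry = AuditEntry(
            seq=seq,
            timestamp=timestamp,
            user=user,
            action=action,
            subject=subject,
            outcome=outcome,
            detail=detail,
            prev_hash=prev_hash,
            hash=_entry_hash(prev_hash, core),
        )
        self.audit.append(entry)
        return entry

    def audit_denied(self, user: str, action: str, subject: str, detail: dict) -> None:
        """Record a denied attempt (called by the engine on permission failure)."""
        self._append_audit(user, action, subject, detail, outcome="denied")

    def verify_chain(self) -> bool:
        """Recompute the hash chain; raise :class:`IntegrityError` on tamper."""
        prev_hash = ""
        for index, entry in enumerate(self.audit, start=1):
            if entry.seq != index:
                raise IntegrityError(
                    f"audit sequence broken at entry {index} (seq={entry.seq})"
                )
            core = {
                "seq": entry.seq,
                "timestamp": entry.timestamp,
                "user": entry.user,
                "action": entry.action,
                "subject": entry.subject,
                "outcome": entry.outcome,
                "detail": entry.detail,
            }
            if entry.prev_hash != prev_hash or entry.hash != _entry_hash(
                prev_hash, core
            ):
                raise IntegrityError(f"audit hash chain broken at entry {index}")
            prev_hash = entry.hash
        return True

    def audit_log(
        self,
        requester: str | None = None,
        case_id: int | None = None,
        user: str | None = None,
        action: str | None = None,
    ) -> list[AuditEntry]:
        """Entries in sequence order, optionally filtered.

        When ``requester`` is given, that user must hold a read right on at
        least one workflow; ``None`` means a trusted in-process caller.
        """
        if requester is not None and not self._has_any_read(requester):
            raise PermissionDenied(f"user {requester!r} may not read the audit log")
        entries = self.audit
        if case_id is not None:
            entries = [e for e in entries if e.detail.get("case_id") == case_id]
        if user is not None:
            entries = [e for e in entries if e.user == user]
        if action is not None:
            entries = [e for e in entries if e.action == action]
        return list(entries)

    def _has_any_read(self, user_id: str) -> bool:
        u = self.users.get(user_id)
        if u is None:
            return False
        return any(p.role == u.role and READ in p.rights for p in self.permissions)

    # -- workflows and registries -----------------------------------------

    def add_workflow(self, wf: WorkflowDefinition) -> None:
        """Register a workflow; live registry state starts from its defaults.

        Re-adding a known workflow id refreshes the definition but keeps the
        live registry entries (appended treatments must survive a reload).
        """
        self.workflows[wf.workflow_id] = wf
        live = self.registries.setdefault(wf.workflow_id, {})
        for name, reg in wf.registries.items():
            if name not in live:
                live[name] = reg

    def has_workflow(self, workflow_id: str) -> bool:
        return workflow_id in self.workflows

    def get_workflow(self, workflow_id: str) -> WorkflowDefinition:
        if workflow_id not in self.workflows:
            raise UnknownWorkflow(f"workflow {workflow_id!r} is not loaded")
        return self.workflows[workflow_id]

    def registries_for(self, workflow_id: str) -> dict[str, RegistryDef]:
        return self.registries.get(workflow_id, {})

    def append_registry_entry(
        self, workflow_id: str, registry_name: str, value: str, user: str
    ) -> RegistryDef:
        """Append ``value`` to an extensible registry (idempotent on duplicates)."""
        live = self.registries.get(workflow_id, {})
        if registry_name not in live:
            raise UnknownRegistry(
                f"workflow {workflow_id!r} has no registry {registry_name!r}"
            )
        if not self.check_permission(user, workflow_id, "*", WRITE):
            self.audit_denied(
                user,
                "append-registry",
                f"registry:{registry_name}",
                {"workflow_id": workflow_id, "registry": registry_name, "value": value},
            )
            raise PermissionDenied(
                f"user {user!r} may not extend registries of {workflow_id!r}"
            )
        reg = live[registry_name]
        if not reg.extensible:
            raise RegistryNotExtensible(
                f"registry {registry_name!r} is not extensible"
            )
        duplicate = value in reg.entries
        if not duplicate:
            reg = RegistryDef(
                registry_name=reg.registry_name,
                entries=reg.entries + (value,),
                extensible=reg.extensible,
            )
            live[registry_name] = reg
        self._append_audit(
            user,
            "append-registry",
            f"registry:{registry_name}",
            {
                "workflow_id": workflow_id,
                "registry": registry_name,
                "value": value,
                "noop": duplicate,
            },
        )
        return reg

    # -- users and permissions --------------------------------------------

    def add_user(self, user: User, actor: str = "system") -> None:
        """Create a user; re-adding the same user id is a silent no-op."""
        if user.user_id in self.users:
            return
        self.users[user.user_id] = user
        self._append_audit(
            actor,
            "create-user",
            f"user:{user.user_id}",
            {"user_id": user.user_id, "name": user.name, "role": user.role},
        )

    def grant_permission(self, permission: Permission, actor: str = "system") -> None:
        """Grant a permission; granting an identical one again is a no-op."""
        if permission in self.permissions:
            return
        self.permissions.append(permission)
        self._append_audit(
            actor,
            "grant-permission",
            f"role:{permission.role}",
            {
                "role": permission.role,
                "workflow_id": permission.workflow_id,
                "activity_id": permission.activity_id,
                "rights": sorted(permission.rights),
            },
        )

    def check_permission(
        self, user_id: str, workflow_id: str, activity_id: str, right: str
    ) -> bool:
        """Default deny: allow only if some grant matches role, workflow,
        activity (exact or wildcard) and includes the right."""
        user = self.users.get(user_id)
        if user is None:
            return False
        for p in self.permissions:
            if (
                p.role == user.role
                and p.workflow_id in ("*", workflow_id)
                and p.activity_id in ("*", activity_id)
                and right in p.rights
            ):
                return True
        return False

    # -- cases -------------------------------------------------------------

    def next_case_id(self) -> int:
        return 1 + max(self.cases, default=0)

    def create_case(self, workflow_id: str, user: str) -> PatientCase:
        if workflow_id not in self.workflows:
            raise UnknownWorkflow(f"workflow {workflow_id!r} is not loaded")
        case = PatientCase(
            case_id=self.next_case_id(),
            workflow_id=workflow_id,
            created_at=self.now(),
        )
        self.cases[case.case_id] = case
        self._append_audit(
            user,
            "create-case",
            f"case:{case.case_id}",
            {"case_id": case.case_id, "workflow_id": workflow_id},
        )
        return case

    def get_case(self, case_id: int) -> PatientCase:
        if case_id not in self.cases:
            raise UnknownCase(f"no case with id {case_id}")
        return self.cases[case_id]

    def add_execution(
        self, case_id: int, execution: ActivityExecution, user: str, raw_values
    ) -> None:
        """Append a validated execution plus its single audit entry.

        ``raw_values`` (the submitted text) goes into the audit detail so the
        log can be replayed through full validation from an empty store.
        """
        case = self.get_case(case_id)
        case.executions.append(execution)
        self._append_audit(
            user,
            "execute-activity",
            f"case:{case_id}/activity:{execution.activity_id}",
            {
                "case_id": case_id,
                "activity_id": execution.activity_id,
                "version": execution.version,
                "attributes": sorted(execution.values),
                "raw": _encode_raw(raw_values),
            },
        )

    def record_batch(self, user: str, summary_detail: dict) -> None:
        self._append_audit(user, "batch-execute", "batch", summary_detail)

    # -- serialization -----------------------------------------------------

    def to_jsonable(self) -> dict:
        from .xpdl_io import serialize_workflow

        return {
            "format": _STORE_FORMAT,
            "workflows": {
                wf_id: serialize_workflow(wf) for wf_id, wf in self.workflows.items()
            },
            "registries": {
                wf_id: {
                    name: {
                        "entries": list(reg.entries),
                        "extensible": reg.extensible,
                    }
                    for name, reg in regs.items()
                }
                for wf_id, regs in self.registries.items()
            },
            "cases": [
                {
                    "case_id": case.case_id,
                    "workflow_id": case.workflow_id,
                    "created_at": case.created_at,
                    "executions": [
                        {
                            "activity_id": e.activity_id,
                            "version": e.version,
                            "executed_at": e.executed_at,
                            "executed_by": e.executed_by,
                            "values": {
                                name: encode_attribute_value(av)
                                for name, av in e.values.items()
                            },
                        }
                        for e in case.executions
                    ],
                }
                for _, case in sorted(self.cases.items())
            ],
            "users": [
                {"user_id": u.user_id, "name": u.name, "role": u.role}
                for u in self.users.values()
            ],
            "permissions": [
                {
                    "role": p.role,
                    "workflow_id": p.workflow_id,
                    "activity_id": p.activity_id,
                    "rights": sorted(p.rights),
                }
                for p in self.permissions
            ],
            "audit": [
                {
                    "seq": e.seq,
                    "timestamp": e.timestamp,
                    "user": e.user,
                    "action": e.action,
                    "subject": e.subject,
                    "outcome": e.outcome,
                    "detail": e.detail,
                    "prev_hash": e.prev_hash,
                    "hash": e.hash,
                }
                for e in self.audit
            ],
        }

    @classmethod
    def from_jsonable(cls, data: dict, clock=None) -> "Store":
        from .xpdl_io import parse_workflow

        if data.get("format") != _STORE_FORMAT:
            raise IntegrityError(
                f"unrecognized store format {data.get('format')!r}"
            )
        store = cls(clock=clock)
        for wf_id, text in data.get("workflows", {}).items():
            wf = parse_workflow(text)
            store.workflows[wf_id] = wf
        for wf_id, regs in data.get("registries", {}).items():
            store.registries[wf_id] = {
                name: RegistryDef(
                    registry_name=name,
                    entries=tuple(spec["entries"]),
                    extensible=spec["extensible"],
                )
                for name, spec in regs.items()
            }
        for u in data.get("users", []):
            store.users[u["user_id"]] = User(**u)
        for p in data.get("permissions", []):
            store.permissions.append(
                Permission(
                    role=p["role"],
                    workflow_id=p["workflow_id"],
                    activity_id=p["activity_id"],
                    rights=frozenset(p["rights"]),
                )
            )
        for c in data.get("cases", []):
            case = PatientCase(
                case_id=c["case_id"],
                workflow_id=c["workflow_id"],
                created_at=c["created_at"],
            )
            for e in c.get("executions", []):
                case.executions.append(
                    ActivityExecution(
                        activity_id=e["activity_id"],
                        version=e["version"],
                        executed_at=e["executed_at"],
                        executed_by=e["executed_by"],
                        values={
                            name: decode_attribute_value(av)
                            for name, av in e["values"].items()
                        },
                    )
                )
            store.cases[case.case_id] = case
        for e in data.get("audit", []):
            store.audit.append(AuditEntry(**e))
        return store

    def save(self, path) -> None:
        payload = json.dumps(self.to_jsonable(), indent=1, sort_keys=True)
        Path(path).write_text(payload, encoding="utf-8")

    @classmethod
    def load(cls, path, clock=None) -> "Store":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls.from_jsonable(data, clock=clock)

    # -- snapshot / restore -------------------------------------------------

    def snapshot(self, destination) -> None:
        """Write a self-contained archive (store + integrity manifest)."""
        payload = json.dumps(self.to_jsonable(), indent=1, sort_keys=True)
        digest = hashlib.sha256(payload.encode("utf-8")).hexdigest()
        with zipfile.ZipFile(destination, "w", zipfile.ZIP_DEFLATED) as archive:
            archive.writestr("store.json", payload)
            archive.writestr(
                "integrity.json",
                json.dumps({"format": _STORE_FORMAT, "sha256": digest}),
            )

    @classmethod
    def restore(cls, source, clock=None) -> "Store":
        """Rebuild a store from a snapshot; all-or-nothing.

        Any corruption — truncated zip, missing member, digest mismatch,
        broken audit chain — raises :class:`IntegrityError` and nothing is
        restored.
        """
        try:
            with zipfile.ZipFile(source) as archive:
                payload = archive.read("store.json").decode("utf-8")
                manifest = json.loads(archive.read("integrity.json"))
        except (zipfile.BadZipFile, KeyError, OSError, ValueError) as exc:
            raise IntegrityError(f"snapshot archive unreadable: {exc}") from exc
        digest = hashlib.sha256(payload.encode("utf-8")).hexdigest()
        if manifest.get("sha256") != digest:
            raise IntegrityError("snapshot digest mismatch")
        store = cls.from_jsonable(json.loads(payload), clock=clock)
        store.verify_chain()
        return store

    # -- replay --------------------------------------------------------------

    def replay(self) -> "Store":
        """Rebuild a store from the audit journal alone.

        Workflow definitions are carried over (loading a workflow is
        configuration, not a patient-data mutation, so it is not journaled);
        every ok-outcome create/execute/append/user/grant entry is re-applied
        through the public operations. The result's latest values equal the
        live store's.
        """
        from . import engine

        replayed = Store(clock=TickClock())
        for wf in self.workflows.values():
            replayed.add_workflow(wf)
        for entry in self.audit:
            if entry.outcome != "ok":
                continue
            detail = entry.detail
            if entry.action == "create-user":
                replayed.add_user(
                    User(
                        user_id=detail["user_id"],
                        name=detail["name"],
                        role=detail["role"],
                    ),
                    actor=entry.user,
                )
            elif entry.action == "grant-permission":
                replayed.grant_permission(
                    Permission(
                        role=detail["role"],
                        workflow_id=detail["workflow_id"],
                        activity_id=detail["activity_id"],
                        rights=frozenset(detail["rights"]),
                    ),
                    actor=entry.user,
                )
            elif entry.action == "create-case":
                replayed.create_case(detail["workflow_id"], entry.user)
            elif entry.action == "execute-activity":
                wf = replayed.get_workflow(
                    replayed.get_case(detail["case_id"]).workflow_id
                )
                engine.execute_activity(
                    replayed,
                    wf,
                    detail["case_id"],
                    detail["activity_id"],
                    _decode_raw(detail["raw"]),
                    entry.user,
                )
            elif entry.action == "append-registry":
                replayed.append_registry_entry(
                    detail["workflow_id"],
                    detail["registry"],
                    detail["value"],
                    entry.user,
                )
        return replayed


def _encode_raw(raw_values) -> dict:
    encoded: dict = {}
    for name, value in raw_values.items():
        if value is None:
            continue
        if isinstance(value, str):
            encoded[name] = value
        else:  # table: sequence of column → text mappings
            encoded[name] = [dict(row) for row in value]
    return encoded


def _decode_raw(data: dict) -> dict:
    return {
        name: (value if isinstance(value, str) else [dict(r) for r in value])
        for name, value in data.items()
    }
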