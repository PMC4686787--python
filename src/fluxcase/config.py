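"""Configuration loading for the command-line interface.

A YAML key-value file supplies the store location and the users, roles and
permissions (authentication proper is a deployment concern; the CLI asserts
identity via ``--user`` and the permission table decides what that identity
may do). Discovery precedence: explicit ``--config`` flag, then the
``FLUXCASE_CONFIG`` environment entry, then ``./fluxcase.yaml``, then
defaults.

Example::

    store: clinic_store.json
    log_level: INFO
    users:
      - {id: dra, name: Dr. A, role: physician}
      - {id: sec, name: Front desk, role: clerk}
    permissions:
      - {role: physician, workflow: "*", activity: "*", rights: [read, write]}
      - {role: clerk, workflow: nmo, activity: identification, rights: [read]}
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .store import Permission, Store, User

__all__ = ["Config", "load_config", "apply_config"]

DEFAULT_STORE = "fluxcase_store.json"


@dataclass
class Config:
    store_path: str = DEFAULT_STORE
    log_level: str = "INFO"
    users: list[User] = field(default_factory=list)
    permissions: list[Permission] = field(default_factory=list)
    source: str | None = None  # where the config was read from, for logging


def _parse(data: dict, source: str | None) -> Config:
    users = [
        User(user_id=str(u["id"]), name=str(u.get("name", u["id"])), role=str(u["role"]))
        for u in data.get("users", [])
    ]
    permissions = [
        Permission(
            role=str(p["role"]),
            workflow_id=str(p.get("workflow", "*")),
            activity_id=str(p.get("activity", "*")),
            rights=frozenset(str(r) for r in p.get("rights", [])),
        )
        for p in data.get("permissions", [])
    ]
    return Config(
        store_path=str(data.get("store", DEFAULT_STORE)),
        log_level=str(data.get("log_level", "INFO")),
        users=users,
        permissions=permissions,
        source=source,
    )


def load_config(explicit_path: str | None = None, env=None) -> Config:
    env = os.environ if env is None else env
    path: Path | None = None
    if explicit_path:
        path = Path(explicit_path)
        if not path.exists():
            raise FileNotFoundError(f"config file {explicit_path!r} not found")
    elif env.get("FLUXCASE_CONFIG"):
        path = Path(env["FLUXCASE_CONFIG"])
        if not path.exists():
            raise FileNotFoundError(
                f"FLUXCASE_CONFIG points at missing file {str(path)!r}"
            )
    elif Path("fluxcase.yaml").exists():
        path = Path("fluxcase.yaml")
    if path is None:
        return Config()
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {str(path)!r} must be a mapping")
    return _parse(data, str(path))


def apply_config(store: Store, config: Config) -> None:
    """Ensure configured users and permissions exist (idempotent)."""
    for user in config.users:
        store.add_user(user, actor="config")
    for permission in config.permissions:
        store.grant_permission(permission, actor="config")
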