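"""Multiuser annotation workflow: pools, custody, rights, auto-versioning.

A workflow is declared in YAML (optionally embedded under the ``workflow:``
key of the project descriptor).  It names users with roles, a set of
*pools* (queues such as ``analyst``, ``reviewer``, ``scientist``), and per
role the pools a user may acquire series from and the pools/users they may
assign series to.  Unannotated series start in ``initial_pool``.

Custody of a series is exclusive: at any moment it is either waiting in
exactly one pool or owned (locked) by exactly one user, never both.  Only
the owner may edit; every voxel/text operator consults :func:`can_edit`.
Releasing a series — back to a pool or to a specific user — is the
ownership-change event and automatically commits an annotation version, so
the state a series left one user's hands in is always recoverable.

Custody mutations go through a per-record serialization guard: a mutation
started on a stale custody snapshot raises rather than silently clobbering
a concurrent change.

Example YAML::

    users:
      - {id: analyst1, role: analyst}
      - {id: reviewer1, role: reviewer}
      - {id: scientist1, role: scientist}
    pools: [analyst, reviewer, scientist]
    rights:
      analyst:
        may_acquire_from: [analyst]
        may_assign_to: [analyst, reviewer]
      reviewer:
        may_acquire_from: [reviewer]
        may_assign_to: [scientist, analyst, "user:*"]
      scientist:
        may_acquire_from: [scientist]
        may_assign_to: [scientist]
    initial_pool: analyst
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .core import Project
from .errors import ContentionError, PermissionDeniedError, ValidationError

__all__ = [
    "Right",
    "WorkflowSpec",
    "SeriesCustody",
    "parse_workflow",
    "workflow_to_dict",
    "init_custody",
    "get_custody",
    "acquire",
    "release",
    "can_edit",
]

_seq = itertools.count(1)  # custody mutation tickets


@dataclass
class Right:
    may_acquire_from: list[str] = field(default_factory=list)
    may_assign_to_pools: list[str] = field(default_factory=list)
    may_assign_to_users: list[str] = field(default_factory=list)  # ids, or "*"


@dataclass
class WorkflowSpec:
    users: dict[str, str]  # user_id -> role
    pools: list[str]
    rights: dict[str, Right]  # role -> Right
    user_rights: dict[str, Right]  # per-user overrides
    initial_pool: str

    def right_for(self, user: str) -> Right:
        if user in self.user_rights:
            return self.user_rights[user]
        role = self.users.get(user)
        if role is None:
            raise PermissionDeniedError(f"user {user!r} is not declared in the workflow")
        return self.rights.get(role, Right())


@dataclass
class SeriesCustody:
    """Exclusive custody record: in a pool XOR owned by a user."""

    series_id: str
    pool: Optional[str] = None
    owner: Optional[str] = None
    locked: bool = False
    _ticket: int = 0  # serialization guard: bumped on every mutation

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        if (self.pool is None) == (self.owner is None):
            raise ValidationError(
                f"series {self.series_id!r} must be in exactly one pool or owned by exactly one user"
            )
        if self.locked and self.owner is None:
            raise ValidationError("locked custody requires an owner")


def _parse_right(doc: dict, pools: set[str], users: set[str], where: str) -> Right:
    acquire_from = list(doc.get("may_acquire_from", []))
    for p in acquire_from:
        if p not in pools:
            raise ValidationError(f"{where}: may_acquire_from names undeclared pool {p!r}")
    to_pools, to_users = [], []
    for target in doc.get("may_assign_to", []):
        if isinstance(target, str) and target.startswith("user:"):
            uid = target[5:]
            if uid != "*" and uid not in users:
                raise ValidationError(f"{where}: may_assign_to names undeclared user {uid!r}")
            to_users.append(uid)
        elif isinstance(target, dict) and "user" in target:
            uid = target["user"]
            if uid != "*" and uid not in users:
                raise ValidationError(f"{where}: may_assign_to names undeclared user {uid!r}")
            to_users.append(uid)
        else:
            if target not in pools:
                raise ValidationError(f"{where}: may_assign_to names undeclared pool {target!r}")
            to_pools.append(target)
    return Right(acquire_from, to_pools, to_users)


def parse_workflow(source: Union[str, dict]) -> WorkflowSpec:
    """Parse and validate a workflow from YAML text or a pre-parsed dict."""
    doc = yaml.safe_load(source) if isinstance(source, str) else source
    if not isinstance(doc, dict):
        raise ValidationError("workflow document must be a mapping")

    raw_users = doc.get("users") or []
    if not raw_users:
        raise ValidationError("workflow must declare at least one user")
    users: dict[str, str] = {}
    for u in raw_users:
        uid, role = u["id"], u["role"]
        if uid in users:
            raise ValidationError(f"duplicate user id {uid!r}")
        users[uid] = role

    pools = list(doc.get("pools") or [])
    if not pools:
        raise ValidationError("workflow must declare at least one pool")
    pool_set, user_set = set(pools), set(users)

    initial_pool = doc.get("initial_pool")
    if initial_pool is None:
        raise ValidationError("workflow must declare initial_pool")
    if initial_pool not in pool_set:
        raise ValidationError(f"initial_pool {initial_pool!r} is not a declared pool")

    rights: dict[str, Right] = {}
    user_rights: dict[str, Right] = {}
    roles = set(users.values())
    for key, rdoc in (doc.get("rights") or {}).items():
        if key.startswith("user:"):
            uid = key[5:]
            if uid not in user_set:
                raise ValidationError(f"rights override for undeclared user {uid!r}")
            user_rights[uid] = _parse_right(rdoc, pool_set, user_set, f"rights[{key}]")
        else:
            if key not in roles:
                raise ValidationError(f"rights declared for unknown role {key!r}")
            rights[key] = _parse_right(rdoc, pool_set, user_set, f"rights[{key}]")

    return WorkflowSpec(
        users=users, pools=pools, rights=rights, user_rights=user_rights, initial_pool=initial_pool
    )


def workflow_to_dict(spec: WorkflowSpec) -> dict:
    """Inverse of :func:`parse_workflow`, for embedding in the project YAML."""

    def right_doc(r: Right) -> dict:
        return {
            "may_acquire_from": list(r.may_acquire_from),
            "may_assign_to": list(r.may_assign_to_pools)
            + [f"user:{u}" for u in r.may_assign_to_users],
        }

    return {
        "users": [{"id": u, "role": role} for u, role in spec.users.items()],
        "pools": list(spec.pools),
        "rights": {
            **{role: right_doc(r) for role, r in spec.rights.items()},
            **{f"user:{u}": right_doc(r) for u, r in spec.user_rights.items()},
        },
        "initial_pool": spec.initial_pool,
    }


# ---------------------------------------------------------------------------
# custody transitions
# ---------------------------------------------------------------------------

def init_custody(project: Project) -> None:
    """Place every series without a custody record into the initial pool."""
    spec: WorkflowSpec = project.workflow  # type: ignore[assignment]
    if spec is None:
        raise ValidationError("project has no workflow attached")
    for s in project.series:
        project.custody.setdefault(
            s.series_id, SeriesCustody(series_id=s.series_id, pool=spec.initial_pool)
        )


def get_custody(project: Project, series_id: str) -> SeriesCustody:
    spec: WorkflowSpec = project.workflow  # type: ignore[assignment]
    custody = project.custody.get(series_id)
    if custody is None and spec is not None:
        custody = SeriesCustody(series_id=series_id, pool=spec.initial_pool)
        project.custody[series_id] = custody
    return custody


def _mutate(custody: SeriesCustody, expected_ticket: Optional[int]) -> None:
    # "no two mutations observe the same prior state": a caller may pass the
    # ticket it read; a stale ticket means someone else mutated in between.
    if expected_ticket is not None and expected_ticket != custody._ticket:
        raise ContentionError(
            f"custody of {custody.series_id!r} changed concurrently; re-read and retry"
        )
    custody._ticket = next(_seq)


def acquire(
    spec: WorkflowSpec,
    custody: SeriesCustody,
    user: str,
    expected_ticket: Optional[int] = None,
) -> SeriesCustody:
    """Take exclusive custody of a pooled series.

    Allowed when the series sits in a pool the user's rights permit
    acquiring from; an already-owned series raises contention.
    """
    if custody.owner is not None:
        raise ContentionError(
            f"series {custody.series_id!r} is already owned by {custody.owner!r}"
        )
    right = spec.right_for(user)
    if custody.pool not in right.may_acquire_from:
        raise PermissionDeniedError(
            f"user {user!r} may not acquire from pool {custody.pool!r}"
        )
    _mutate(custody, expected_ticket)
    custody.pool = None
    custody.owner = user
    custody.locked = True
    custody._check()
    return custody


def release(
    spec: WorkflowSpec,
    custody: SeriesCustody,
    user: str,
    target: Union[str, tuple[str, str]],
    project: Optional[Project] = None,
    expected_ticket: Optional[int] = None,
) -> SeriesCustody:
    """Give up custody into a pool or to a specific user (ownership change).

    ``target`` is a pool name, ``("user", user_id)`` or the string
    ``"user:<id>"``.  When a project is supplied, an annotation version is
    committed automatically — exactly one per ownership change.
    """
    if custody.owner != user:
        raise PermissionDeniedError(
            f"user {user!r} does not own series {custody.series_id!r}"
        )
    if isinstance(target, str) and target.startswith("user:"):
        target = ("user", target[5:])
    right = spec.right_for(user)
    if isinstance(target, tuple):
        _, target_user = target
        if target_user not in spec.users:
            raise PermissionDeniedError(f"assignment target user {target_user!r} not declared")
        if "*" not in right.may_assign_to_users and target_user not in right.may_assign_to_users:
            raise PermissionDeniedError(
                f"user {user!r} may not assign series to user {target_user!r}"
            )
        _mutate(custody, expected_ticket)
        custody.owner = target_user
        custody.pool = None
        custody.locked = True
    else:
        if target not in right.may_assign_to_pools:
            raise PermissionDeniedError(
                f"user {user!r} may not assign series to pool {target!r}"
            )
        _mutate(custody, expected_ticket)
        custody.owner = None
        custody.pool = target
        custody.locked = False
    custody._check()

    if project is not None:
        from .io import commit_version

        commit_version(project, custody.series_id, user, note="ownership change")
    return custody


def can_edit(spec: WorkflowSpec, custody: Optional[SeriesCustody], user: Optional[str]) -> bool:
    """True iff ``user`` currently owns the series; pooled series are read-only."""
    return custody is not None and user is not None and custody.owner == user
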