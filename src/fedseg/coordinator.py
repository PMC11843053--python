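"""Central coordinating server: registry, authentication, task metadata,
pull-based work distribution, status bookkeeping — and *only* the final
global model, never intermediates.

The coordinator relays metadata and control messages; weight traffic
flows exclusively between stations and the secure aggregation server.
The one exception, by design, is the single final aggregated model that
the aggregator deposits when the task finishes and that the researcher
may then download.  The storage-audit test scans the store during a live
federation to confirm nothing else ever lands here.

Persistence is an in-memory store with an optional append-only JSONL
journal (``journal_path``): every registration, task event and the final
model (as a base64 weight container) is journalled as one JSON record.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import secrets
import time
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    AccessDeniedError,
    AuthenticationError,
    AuthorizationError,
    ChannelViolationError,
    ConfigurationError,
    ConflictError,
    NotFoundError,
    StateError,
)
from .training import TrainMetrics
from .weights import WeightSet, deserialize_weights_bytes, serialize_weights_bytes

ROLES = ("researcher", "station", "aggregator")

# role allow-list per operation; anything absent is rejected
_PERMISSIONS: dict[str, frozenset] = {
    "submit_task": frozenset({"researcher"}),
    "check_status": frozenset({"researcher", "station", "aggregator"}),
    "pull_work": frozenset({"station", "aggregator"}),
    "report_status": frozenset({"station", "aggregator"}),
    "store_final_model": frozenset({"aggregator"}),
    "fetch_final_model": frozenset({"researcher"}),
}

_PBKDF2_ITERATIONS = 20_000
SESSION_LIFETIME_S = 3600.0
LEASE_TIMEOUT_S = 600.0


@dataclass(frozen=True)
class Entity:
    entity_id: str
    role: str
    salt: bytes
    digest: bytes  # PBKDF2-HMAC-SHA256; no recoverable plaintext anywhere


@dataclass(frozen=True)
class Session:
    token: str
    entity_id: str
    role: str
    expires_at: float


@dataclass(frozen=True)
class TaskSpec:
    """Researcher-submitted task description."""

    task_id: str
    algorithm_ref: str
    input_params: dict
    n_iterations: int
    aggregator_id: str
    station_ids: tuple[str, ...]

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be a positive integer")
        if not self.station_ids:
            raise ConfigurationError("station roster must be non-empty")
        if len(set(self.station_ids)) != len(self.station_ids):
            raise ConfigurationError("duplicate station in roster")

    def as_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "algorithm_ref": self.algorithm_ref,
            "input_params": dict(self.input_params),
            "n_iterations": self.n_iterations,
            "aggregator_id": self.aggregator_id,
            "station_ids": list(self.station_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        return cls(
            task_id=d["task_id"],
            algorithm_ref=d["algorithm_ref"],
            input_params=dict(d["input_params"]),
            n_iterations=int(d["n_iterations"]),
            aggregator_id=d["aggregator_id"],
            station_ids=tuple(d["station_ids"]),
        )


@dataclass
class WorkItem:
    item_id: str
    task_id: str
    kind: str  # "master" | "subtask"
    assignee: str
    lease_expires_at: float | None = None
    completed: bool = False

    def as_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "task_id": self.task_id,
            "kind": self.kind,
            "assignee": self.assignee,
        }


_ALLOWED_TRANSITIONS = {
    ("pending", "running"),
    ("running", "completed"),
    ("running", "aborted"),
    ("pending", "completed"),  # single-call report without an explicit pull
    ("pending", "aborted"),
    ("aborted", "pending"),  # re-open after dropout recovery
    ("completed", "pending"),  # re-open discards the whole iteration
    ("completed", "completed"),  # idempotent re-report
}


@dataclass
class TaskRecord:
    spec: TaskSpec
    overall: str = "created"  # created | running | finished | aborted
    cell_status: dict = field(default_factory=dict)  # (iteration, entity) -> state
    history: list = field(default_factory=list)  # TrainMetrics dicts + events
    final_model_blob: bytes | None = None


class Coordinator:
    """In-memory central server; all operations take a session credential."""

    def __init__(self, journal_path=None, clock=time.time):
        self._entities: dict[str, Entity] = {}
        self._sessions: dict[str, Session] = {}
        self._tasks: dict[str, TaskRecord] = {}
        self._queue: list[WorkItem] = []
        self._clock = clock
        self._journal_path = Path(journal_path) if journal_path else None
        self.request_log: list[dict] = []

    # -- journal -------------------------------------------------------

    def _journal(self, record: dict) -> None:
        if self._journal_path is None:
            return
        with open(self._journal_path, "a") as fh:
            fh.write(json.dumps(record, sort_keys=True) + "\n")

    def _log(self, entity: str, route: str, outcome: str) -> None:
        self.request_log.append(
            {"entity": entity, "route": route, "outcome": outcome, "t": self._clock()}
        )

    # -- registry and authentication ------------------------------------

    def register_entity(self, entity_id: str, role: str, password: str) -> dict:
        if role not in ROLES:
            raise ConfigurationError(f"unknown role {role!r}")
        if entity_id in self._entities:
            raise ConflictError(f"entity {entity_id!r} already registered")
        salt = secrets.token_bytes(16)
        digest = hashlib.pbkdf2_hmac(
            "sha256", password.encode(), salt, _PBKDF2_ITERATIONS
        )
        self._entities[entity_id] = Entity(entity_id, role, salt, digest)
        self._journal({"event": "register", "entity_id": entity_id, "role": role})
        self._log(entity_id, "register", "ok")
        return {"entity_id": entity_id, "role": role}

    def authenticate(self, entity_id: str, password: str) -> Session:
        entity = self._entities.get(entity_id)
        if entity is None:
            # burn comparable work so unknown-user and wrong-password paths
            # are the same error type and similar timing
            hashlib.pbkdf2_hmac(
                "sha256", password.encode(), b"\x00" * 16, _PBKDF2_ITERATIONS
            )
            self._log(entity_id, "authenticate", "denied")
            raise AuthenticationError("authentication failed")
        digest = hashlib.pbkdf2_hmac(
            "sha256", password.encode(), entity.salt, _PBKDF2_ITERATIONS
        )
        if not hmac.compare_digest(digest, entity.digest):
            self._log(entity_id, "authenticate", "denied")
            raise AuthenticationError("authentication failed")
        session = Session(
            token=secrets.token_hex(16),
            entity_id=entity_id,
            role=entity.role,
            expires_at=self._clock() + SESSION_LIFETIME_S,
        )
        self._sessions[session.token] = session
        self._log(entity_id, "authenticate", "ok")
        return session

    def _require(self, session: Session, operation: str) -> Session:
        live = self._sessions.get(getattr(session, "token", None))
        if live is None or live.entity_id != session.entity_id:
            raise AuthenticationError("invalid session: re-authentication required")
        if self._clock() > live.expires_at:
            del self._sessions[live.token]
            raise AuthenticationError("session expired: re-authentication required")
        if live.role not in _PERMISSIONS.get(operation, frozenset()):
            self._log(live.entity_id, operation, "forbidden")
            raise AuthorizationError(
                f"role {live.role!r} may not perform {operation!r}"
            )
        return live

    # -- task lifecycle --------------------------------------------------

    def submit_task(self, session: Session, task: TaskSpec) -> dict:
        live = self._require(session, "submit_task")
        if task.task_id in self._tasks:
            raise ConflictError(f"task {task.task_id!r} already exists")
        agg = self._entities.get(task.aggregator_id)
        if agg is None or agg.role != "aggregator":
            raise ConfigurationError(
                f"aggregator {task.aggregator_id!r} is not a registered aggregator"
            )
        for sid in task.station_ids:
            st = self._entities.get(sid)
            if st is None or st.role != "station":
                raise ConfigurationError(f"station {sid!r} is not a registered station")
        record = TaskRecord(spec=task, overall="created")
        for it in range(task.n_iterations):
            record.cell_status[(it, task.aggregator_id)] = "pending"
            for sid in task.station_ids:
                record.cell_status[(it, sid)] = "pending"
        self._tasks[task.task_id] = record
        # master request first (the SAS is the first to receive the task),
        # then one subtask per station
        self._queue.append(
            WorkItem(f"{task.task_id}/master", task.task_id, "master", task.aggregator_id)
        )
        for sid in task.station_ids:
            self._queue.append(
                WorkItem(f"{task.task_id}/sub/{sid}", task.task_id, "subtask", sid)
            )
        self._journal({"event": "task_submitted", "task": task.as_dict()})
        self._log(live.entity_id, "submit_task", "ok")
        return self.check_status(session, task.task_id)

    def get_task(self, task_id: str) -> TaskSpec:
        record = self._tasks.get(task_id)
        if record is None:
            raise NotFoundError(f"unknown task {task_id!r}")
        return record.spec

    def pull_work(self, session: Session) -> list[dict]:
        live = self._require(session, "pull_work")
        now = self._clock()
        items = []
        for item in self._queue:
            if item.completed or item.assignee != live.entity_id:
                continue
            if item.lease_expires_at is None or now > item.lease_expires_at:
                item.lease_expires_at = now + LEASE_TIMEOUT_S
            items.append(item.as_dict())  # re-pull within lease returns same item
        self._log(live.entity_id, "pull_work", f"{len(items)} items")
        return items

    def complete_work(self, session: Session, item_id: str) -> None:
        live = self._require(session, "pull_work")
        for item in self._queue:
            if item.item_id == item_id and item.assignee == live.entity_id:
                item.completed = True
                return
        raise NotFoundError(f"no work item {item_id!r} for {live.entity_id!r}")

    # -- status and history ----------------------------------------------

    @staticmethod
    def _looks_like_weights(metrics) -> bool:
        if isinstance(metrics, WeightSet):
            return True
        if isinstance(metrics, dict) and (
            "entries" in metrics or "payload" in metrics or "weights" in metrics
        ):
            return True
        return False

    def report_status(
        self,
        session: Session,
        task_id: str,
        iteration: int,
        state: str,
        metrics: TrainMetrics | dict | None = None,
    ) -> dict:
        live = self._require(session, "report_status")
        record = self._tasks.get(task_id)
        if record is None:
            raise NotFoundError(f"unknown task {task_id!r}")
        spec = record.spec
        addressed = set(spec.station_ids) | {spec.aggregator_id}
        if live.entity_id not in addressed:
            raise AuthorizationError(
                f"{live.entity_id!r} is not addressed by task {task_id!r}"
            )
        if state not in ("running", "completed", "aborted", "pending"):
            raise ConfigurationError(f"invalid status {state!r}")
        if self._looks_like_weights(metrics):
            raise ChannelViolationError(
                "the status channel does not accept weight payloads"
            )
        key = (iteration, live.entity_id)
        if key not in record.cell_status:
            raise NotFoundError(f"iteration {iteration} outside task range")
        old = record.cell_status[key]
        if old != state and (old, state) not in _ALLOWED_TRANSITIONS:
            raise StateError(f"status regression {old} -> {state} refused")
        record.cell_status[key] = state
        if record.overall == "created":
            record.overall = "running"
        if state == "aborted":
            record.overall = "aborted"
        elif record.overall == "aborted" and state in ("pending", "running"):
            record.overall = "running"  # re-opened after recovery
        if metrics is not None:
            entry = metrics.as_dict() if isinstance(metrics, TrainMetrics) else dict(metrics)
            entry["reported_by"] = live.entity_id
            entry["iteration"] = iteration
            record.history.append(entry)
        self._journal(
            {"event": "status", "task_id": task_id, "iteration": iteration,
             "entity": live.entity_id, "state": state}
        )
        self._log(live.entity_id, "report_status", state)
        return self.check_status(session, task_id)

    def check_status(self, session: Session, task_id: str) -> dict:
        live = self._require(session, "check_status")
        record = self._tasks.get(task_id)
        if record is None:
            raise NotFoundError(f"unknown task {task_id!r}")
        self._log(live.entity_id, "check_status", record.overall)
        return {
            "task_id": task_id,
            "overall": record.overall,
            "cells": {
                f"{it}:{ent}": st for (it, ent), st in sorted(record.cell_status.items())
            },
        }

    def task_history(self, task_id: str) -> list[dict]:
        record = self._tasks.get(task_id)
        if record is None:
            raise NotFoundError(f"unknown task {task_id!r}")
        return list(record.history)

    # -- final model (the only weight payload this server ever holds) ----

    def store_final_model(self, session: Session, task_id: str, weights: WeightSet) -> dict:
        live = self._require(session, "store_final_model")
        record = self._tasks.get(task_id)
        if record is None:
            raise NotFoundError(f"unknown task {task_id!r}")
        if live.entity_id != record.spec.aggregator_id:
            raise AuthorizationError("only the task's aggregator may store the final model")
        if record.final_model_blob is not None:
            raise ConflictError(f"final model for {task_id!r} already stored")
        last = record.spec.n_iterations - 1
        if weights.meta.iteration != last:
            raise StateError(
                f"refusing mid-task store: model is from iteration "
                f"{weights.meta.iteration}, task ends at {last}"
            )
        incomplete = [
            (it, ent)
            for (it, ent), st in record.cell_status.items()
            if st not in ("completed",)
        ]
        if incomplete:
            raise StateError(
                f"refusing store: {len(incomplete)} task cells not completed"
            )
        blob = serialize_weights_bytes(weights)
        record.final_model_blob = blob
        record.overall = "finished"
        self._journal(
            {
                "event": "final_model",
                "task_id": task_id,
                "sha256": hashlib.sha256(blob).hexdigest(),
                "container_b64": base64.b64encode(blob).decode("ascii"),
            }
        )
        self._log(live.entity_id, "store_final_model", "ok")
        return {"task_id": task_id, "stored_bytes": len(blob)}

    def fetch_final_model(self, session: Session, task_id: str) -> WeightSet:
        live = self._require(session, "fetch_final_model")
        record = self._tasks.get(task_id)
        if record is None:
            raise NotFoundError(f"unknown task {task_id!r}")
        if record.overall != "finished" or record.final_model_blob is None:
            self._log(live.entity_id, "fetch_final_model", "denied")
            raise AccessDeniedError(
                f"task {task_id!r} is not finished; the final model is not "
                "yet available and no intermediate-model route exists"
            )
        self._log(live.entity_id, "fetch_final_model", "ok")
        return deserialize_weights_bytes(record.final_model_blob)

    # -- audit ------------------------------------------------------------

    def audit_stored_weight_payloads(self) -> dict[str, int]:
        """Number of weight payloads held per task (0 until finish, then 1)."""
        return {
            task_id: (0 if rec.final_model_blob is None else 1)
            for task_id, rec in self._tasks.items()
        }
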