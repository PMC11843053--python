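"""In-memory "tracks": the reference transport between federation parties.

Every exchange — station/SAS, station/coordinator, researcher/coordinator —
travels through an :class:`InMemoryTrack` as a serialized frame:

    8 bytes  little-endian uint64 = length of the JSON control segment
    JSON     control message (route fields, tokens, metrics, sessions)
    bytes    optional attachment: exactly one ``.fweights`` weight container

The track records every frame verbatim.  That instrumentation is the
teeth behind the data-locality contract: an audit can decode each frame
and verify that nothing but JSON control data and digest-protected
weight containers ever left a station — in particular, no image or mask
array bytes.  An HTTP binding would implement this same request contract;
at desk scale the in-memory track is the reference implementation.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

import numpy as np

from .coordinator import Coordinator, Session, TaskSpec
from .errors import FormatError
from .weights import WeightSet, deserialize_weights_bytes, serialize_weights_bytes


def encode_frame(control: dict, attachment: bytes | None = None) -> bytes:
    control_bytes = json.dumps(control, sort_keys=True).encode("utf-8")
    return (
        struct.pack("<Q", len(control_bytes))
        + control_bytes
        + (attachment or b"")
    )


def decode_frame(frame: bytes) -> tuple[dict, bytes | None]:
    if len(frame) < 8:
        raise FormatError("truncated frame")
    (n,) = struct.unpack("<Q", frame[:8])
    control = json.loads(frame[8 : 8 + n])
    attachment = frame[8 + n :] or None
    return control, attachment


@dataclass
class TrackFrame:
    direction: str  # "request" | "response"
    sender: str
    recipient: str
    route: str
    frame: bytes

    @property
    def control(self) -> dict:
        return decode_frame(self.frame)[0]

    @property
    def attachment(self) -> bytes | None:
        return decode_frame(self.frame)[1]


class InMemoryTrack:
    """Single-process message bus with full frame recording."""

    def __init__(self):
        self._endpoints: dict[str, object] = {}
        self.log: list[TrackFrame] = []

    def register_endpoint(self, name: str, service) -> None:
        self._endpoints[name] = service

    def request(
        self,
        sender: str,
        recipient: str,
        route: str,
        control: dict,
        attachment: bytes | None = None,
    ) -> tuple[dict, bytes | None]:
        self.log.append(
            TrackFrame("request", sender, recipient, route, encode_frame(control, attachment))
        )
        service = self._endpoints.get(recipient)
        if service is None:
            raise FormatError(f"no endpoint {recipient!r} on this track")
        resp_control, resp_attachment = service.handle(route, control, attachment)
        self.log.append(
            TrackFrame(
                "response", recipient, sender, route, encode_frame(resp_control, resp_attachment)
            )
        )
        return resp_control, resp_attachment

    # -- audit ----------------------------------------------------------

    def frames_sent_by(self, sender: str) -> list[TrackFrame]:
        return [f for f in self.log if f.sender == sender]

    def audit_data_locality(self, cases, expected_manifest=None) -> dict:
        """Verify every recorded frame is JSON control + (optionally) a
        valid weight container, and that no case's raw image/mask bytes
        appear anywhere on the track.  Returns audit counters; raises
        :class:`FormatError` on any violation."""
        n_weights = 0
        forbidden = []
        for case in cases:
            forbidden.append(np.ascontiguousarray(case.image, dtype="<f4").tobytes())
            forbidden.append(np.ascontiguousarray(case.mask, dtype=np.uint8).tobytes())
        for fr in self.log:
            control, attachment = decode_frame(fr.frame)  # raises if not JSON
            if not isinstance(control, dict):
                raise FormatError(f"non-object control message on route {fr.route}")
            if attachment is not None:
                w = deserialize_weights_bytes(attachment)  # must parse as weights
                if expected_manifest is not None and w.manifest() != tuple(expected_manifest):
                    raise FormatError(
                        f"attachment on route {fr.route} is not a task-manifest weight set"
                    )
                n_weights += 1
            for blob in forbidden:
                if blob and blob in fr.frame:
                    raise FormatError(
                        f"raw case array bytes found on track (route {fr.route}, "
                        f"{fr.sender} -> {fr.recipient})"
                    )
        return {"n_frames": len(self.log), "n_weight_attachments": n_weights}


# ---------------------------------------------------------------------------
# services: thin adapters from track frames to the in-process servers
# ---------------------------------------------------------------------------

class SASService:
    """Track endpoint wrapping a :class:`SecureAggregationServer`."""

    def __init__(self, sas):
        self.sas = sas

    def handle(self, route: str, control: dict, attachment: bytes | None):
        if route == "request-token":
            token = self.sas.request_token(control["task_id"], control["station_id"])
            return {"token": token}, None
        if route == "get-global-model":
            w = self.sas.release_global_model(control["task_id"], control["token"])
            return {"iteration": w.meta.iteration}, serialize_weights_bytes(w)
        if route == "submit-model":
            if attachment is None:
                raise FormatError("submit-model requires a weight attachment")
            weights = deserialize_weights_bytes(attachment)
            ack = self.sas.accept_model_submission(
                control["task_id"], control["token"], weights
            )
            return ack, None
        raise FormatError(f"unknown SAS route {route!r}")


class CoordinatorService:
    """Track endpoint wrapping a :class:`Coordinator`."""

    def __init__(self, coordinator: Coordinator):
        self.coordinator = coordinator

    @staticmethod
    def _session(control: dict) -> Session:
        return Session(
            token=control["session_token"],
            entity_id=control["entity_id"],
            role="",
            expires_at=0.0,
        )

    def handle(self, route: str, control: dict, attachment: bytes | None):
        c = self.coordinator
        if route == "register":
            return (
                c.register_entity(control["entity_id"], control["role"], control["password"]),
                None,
            )
        if route == "authenticate":
            s = c.authenticate(control["entity_id"], control["password"])
            return {"session_token": s.token, "role": s.role, "expires_at": s.expires_at}, None
        session = self._session(control)
        if route == "submit-task":
            return c.submit_task(session, TaskSpec.from_dict(control["task"])), None
        if route == "pull-work":
            return {"items": c.pull_work(session)}, None
        if route == "complete-work":
            c.complete_work(session, control["item_id"])
            return {"ok": True}, None
        if route == "report-status":
            return (
                c.report_status(
                    session,
                    control["task_id"],
                    int(control["iteration"]),
                    control["state"],
                    control.get("metrics"),
                ),
                None,
            )
        if route == "check-status":
            return c.check_status(session, control["task_id"]), None
        if route == "store-final-model":
            if attachment is None:
                raise FormatError("store-final-model requires a weight attachment")
            weights = deserialize_weights_bytes(attachment)
            return c.store_final_model(session, control["task_id"], weights), None
        if route == "fetch-final-model":
            w = c.fetch_final_model(session, control["task_id"])
            return {"iteration": w.meta.iteration}, serialize_weights_bytes(w)
        raise FormatError(f"unknown coordinator route {route!r}")


# ---------------------------------------------------------------------------
# clients
# ---------------------------------------------------------------------------

class SASClient:
    """Station-side proxy to the SAS over a track."""

    def __init__(self, track: InMemoryTrack, sas_endpoint: str, sender: str):
        self.track = track
        self.endpoint = sas_endpoint
        self.sender = sender

    def request_token(self, task_id: str, station_id: str) -> str:
        control, _ = self.track.request(
            self.sender, self.endpoint, "request-token",
            {"task_id": task_id, "station_id": station_id},
        )
        return control["token"]

    def get_global_model(self, task_id: str, token: str) -> WeightSet:
        _, attachment = self.track.request(
            self.sender, self.endpoint, "get-global-model",
            {"task_id": task_id, "token": token},
        )
        return deserialize_weights_bytes(attachment)

    def submit_model(self, task_id: str, token: str, weights: WeightSet) -> dict:
        control, _ = self.track.request(
            self.sender, self.endpoint, "submit-model",
            {"task_id": task_id, "token": token},
            serialize_weights_bytes(weights),
        )
        return control


class CoordinatorClient:
    """Any party's proxy to the coordinator over a track."""

    def __init__(self, track: InMemoryTrack, endpoint: str, sender: str):
        self.track = track
        self.endpoint = endpoint
        self.sender = sender
        self._session_token: str | None = None

    def _control(self, extra: dict) -> dict:
        base = {"entity_id": self.sender}
        if self._session_token is not None:
            base["session_token"] = self._session_token
        base.update(extra)
        return base

    def register(self, role: str, password: str) -> dict:
        control, _ = self.track.request(
            self.sender, self.endpoint, "register",
            {"entity_id": self.sender, "role": role, "password": password},
        )
        return control

    def authenticate(self, password: str) -> dict:
        control, _ = self.track.request(
            self.sender, self.endpoint, "authenticate",
            {"entity_id": self.sender, "password": password},
        )
        self._session_token = control["session_token"]
        return control

    def submit_task(self, task: TaskSpec) -> dict:
        control, _ = self.track.request(
            self.sender, self.endpoint, "submit-task",
            self._control({"task": task.as_dict()}),
        )
        return control

    def pull_work(self) -> list[dict]:
        control, _ = self.track.request(
            self.sender, self.endpoint, "pull-work", self._control({})
        )
        return control["items"]

    def complete_work(self, item_id: str) -> None:
        self.track.request(
            self.sender, self.endpoint, "complete-work",
            self._control({"item_id": item_id}),
        )

    def report_status(self, task_id: str, iteration: int, state: str, metrics=None) -> dict:
        control, _ = self.track.request(
            self.sender, self.endpoint, "report-status",
            self._control(
                {
                    "task_id": task_id,
                    "iteration": iteration,
                    "state": state,
                    "metrics": metrics,
                }
            ),
        )
        return control

    def check_status(self, task_id: str) -> dict:
        control, _ = self.track.request(
            self.sender, self.endpoint, "check-status",
            self._control({"task_id": task_id}),
        )
        return control

    def store_final_model(self, task_id: str, weights: WeightSet) -> dict:
        control, _ = self.track.request(
            self.sender, self.endpoint, "store-final-model",
            self._control({"task_id": task_id}),
            serialize_weights_bytes(weights),
        )
        return control

    def fetch_final_model(self, task_id: str) -> WeightSet:
        _, attachment = self.track.request(
            self.sender, self.endpoint, "fetch-final-model",
            self._control({"task_id": task_id}),
        )
        return deserialize_weights_bytes(attachment)
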