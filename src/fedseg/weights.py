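"""Model-weight exchange unit and its digest-protected container format.

A :class:`WeightSet` is the only thing a data station ever sends to the
secure aggregation server: an ordered list of named float32 parameter
arrays plus provenance metadata (task, iteration, origin, number of local
training samples).  Two weight sets are exchangeable within one task iff
their *manifests* — the ordered ``(name, shape)`` pairs — are identical.

On disk (and on the wire) a weight set is a ``.fweights`` container::

    8 bytes   magic  b"FWEIGHT1"
    8 bytes   little-endian uint64, byte length L of the JSON header
    L bytes   UTF-8 JSON header: dtype tag, byteorder, meta, per-entry
              name/shape/offset/nbytes, payload_nbytes, payload_sha256
    N bytes   concatenated little-endian float32 payload

The SHA-256 digest over the payload is verified before any array is
returned, so a truncated or bit-flipped file can never yield a partial
weight set.
"""

from __future__ import annotations

import hashlib
import io
import json
import struct
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .errors import FormatError, IntegrityError, WeightCompatibilityError

_MAGIC = b"FWEIGHT1"
_DTYPE_TAG = "float32"


@dataclass(frozen=True)
class WeightMeta:
    """Provenance carried with every weight set."""

    task_id: str = ""
    iteration: int = 0
    origin: str = "SAS"
    n_train_samples: int = 0

    def as_dict(self) -> dict:
        return {
            "task_id": self.task_id,
            "iteration": int(self.iteration),
            "origin": self.origin,
            "n_train_samples": int(self.n_train_samples),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WeightMeta":
        return cls(
            task_id=str(d.get("task_id", "")),
            iteration=int(d.get("iteration", 0)),
            origin=str(d.get("origin", "SAS")),
            n_train_samples=int(d.get("n_train_samples", 0)),
        )


@dataclass
class WeightSet:
    """Ordered named float32 parameter arrays + provenance metadata."""

    entries: list[tuple[str, np.ndarray]]
    meta: WeightMeta = field(default_factory=WeightMeta)

    def __post_init__(self) -> None:
        fixed = []
        for name, values in self.entries:
            arr = np.asarray(values)
            if arr.dtype != np.float32:
                arr = arr.astype(np.float32)
            fixed.append((str(name), arr))
        self.entries = fixed

    # -- manifest ------------------------------------------------------

    def manifest(self) -> tuple[tuple[str, tuple[int, ...]], ...]:
        """Ordered (name, shape) pairs; the compatibility contract of a task."""
        return tuple((name, tuple(v.shape)) for name, v in self.entries)

    def n_parameters(self) -> int:
        return int(sum(v.size for _, v in self.entries))

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: v for name, v in self.entries}

    def copy(self, **meta_updates) -> "WeightSet":
        """Deep copy; ``meta_updates`` are applied to the metadata."""
        meta = replace(self.meta, **meta_updates) if meta_updates else self.meta
        return WeightSet([(n, v.copy()) for n, v in self.entries], meta)

    def allclose(self, other: "WeightSet", atol: float = 0.0) -> bool:
        if self.manifest() != other.manifest():
            return False
        for (_, a), (_, b) in zip(self.entries, other.entries):
            if atol == 0.0:
                if not np.array_equal(a, b):
                    return False
            elif not np.allclose(a, b, rtol=0.0, atol=atol):
                return False
        return True

    def max_abs_diff(self, other: "WeightSet") -> float:
        require_same_manifest([self, other])
        diffs = [
            float(np.max(np.abs(a.astype(np.float64) - b.astype(np.float64))))
            if a.size
            else 0.0
            for (_, a), (_, b) in zip(self.entries, other.entries)
        ]
        return max(diffs) if diffs else 0.0


def require_same_manifest(weight_sets: Iterable[WeightSet]) -> None:
    """Raise :class:`WeightCompatibilityError` unless all manifests match."""
    ws = list(weight_sets)
    if not ws:
        raise WeightCompatibilityError("no weight sets given")
    ref = ws[0].manifest()
    for w in ws[1:]:
        if w.manifest() != ref:
            raise WeightCompatibilityError(
                f"weight manifests differ: {w.manifest()!r} vs {ref!r}"
            )


# ---------------------------------------------------------------------------
# container serialization
# ---------------------------------------------------------------------------

def serialize_weights_bytes(w: WeightSet) -> bytes:
    """Serialize to the ``.fweights`` container as a byte string."""
    payload = io.BytesIO()
    entries = []
    offset = 0
    for name, values in w.entries:
        raw = np.ascontiguousarray(values, dtype="<f4").tobytes()
        entries.append(
            {
                "name": name,
                "shape": list(values.shape),
                "offset": offset,
                "nbytes": len(raw),
            }
        )
        payload.write(raw)
        offset += len(raw)
    payload_bytes = payload.getvalue()
    header = {
        "format_version": 1,
        "dtype": _DTYPE_TAG,
        "byteorder": "little",
        "meta": w.meta.as_dict(),
        "entries": entries,
        "payload_nbytes": len(payload_bytes),
        "payload_sha256": hashlib.sha256(payload_bytes).hexdigest(),
    }
    header_bytes = json.dumps(header, sort_keys=True).encode("utf-8")
    return _MAGIC + struct.pack("<Q", len(header_bytes)) + header_bytes + payload_bytes


def deserialize_weights_bytes(blob: bytes) -> WeightSet:
    """Parse a ``.fweights`` container, verifying digest and layout first."""
    if len(blob) < len(_MAGIC) + 8 or blob[: len(_MAGIC)] != _MAGIC:
        raise FormatError("not a weight container (bad magic)")
    (header_len,) = struct.unpack("<Q", blob[len(_MAGIC) : len(_MAGIC) + 8])
    header_start = len(_MAGIC) + 8
    if header_start + header_len > len(blob):
        raise FormatError("truncated weight container header")
    try:
        header = json.loads(blob[header_start : header_start + header_len])
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise FormatError(f"unreadable weight container header: {exc}") from exc
    if header.get("dtype") != _DTYPE_TAG:
        raise FormatError(f"unknown dtype tag {header.get('dtype')!r}")
    if header.get("byteorder") != "little":
        raise FormatError(f"unknown byteorder {header.get('byteorder')!r}")
    payload = blob[header_start + header_len :]
    expected_nbytes = int(header["payload_nbytes"])
    if len(payload) != expected_nbytes:
        raise FormatError(
            f"truncated payload: have {len(payload)} bytes, manifest says {expected_nbytes}"
        )
    digest = hashlib.sha256(payload).hexdigest()
    if digest != header["payload_sha256"]:
        raise IntegrityError("payload digest mismatch: container corrupt or tampered")
    entries: list[tuple[str, np.ndarray]] = []
    for e in header["entries"]:
        shape = tuple(int(s) for s in e["shape"])
        nbytes = int(e["nbytes"])
        offset = int(e["offset"])
        n_elem = int(np.prod(shape, dtype=np.int64)) if shape else 1
        if nbytes != 4 * n_elem or offset + nbytes > len(payload):
            raise FormatError(f"inconsistent entry layout for {e['name']!r}")
        arr = np.frombuffer(payload, dtype="<f4", count=n_elem, offset=offset)
        entries.append((str(e["name"]), arr.reshape(shape).copy()))
    return WeightSet(entries, WeightMeta.from_dict(header.get("meta", {})))


def serialize_weights(w: WeightSet, path) -> None:
    """Write ``w`` to ``path`` in the ``.fweights`` container format."""
    blob = serialize_weights_bytes(w)
    with open(path, "wb") as fh:
        fh.write(blob)


def deserialize_weights(path) -> WeightSet:
    """Read a ``.fweights`` container; digest-verified before returning."""
    with open(path, "rb") as fh:
        blob = fh.read()
    return deserialize_weights_bytes(blob)
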