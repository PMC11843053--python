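"""Per-iteration JSON Web Tokens gating every station<->SAS exchange.

Every data station must present a bearer token that is unique to one
``(task, iteration)`` — and, after a dropout re-opens an iteration, to
one *attempt* of that iteration — so a captured token can never be
replayed in a later round.  Tokens are compact JWTs
(``header.payload.signature``, base64url) signed with HMAC-SHA-256 under
a per-task symmetric key shared between coordinator and aggregation
server at task creation.

Validation is pure: it either returns the verified claims or raises a
typed :class:`~fedseg.errors.TokenRejection`; it never mutates any state,
so a refused request is side-effect free by construction.
"""

from __future__ import annotations

import base64
import hmac
import hashlib
import json
import secrets
import time
from dataclasses import dataclass

from .errors import (
    ClaimsError,
    ConfigurationError,
    ExpiredTokenError,
    ForgedTokenError,
    ReplayedTokenError,
    UnknownStationError,
)

CLOCK_SKEW_S = 30.0
DEFAULT_LIFETIME_S = 600.0


@dataclass(frozen=True)
class TokenClaims:
    """Signed claims binding a token to one station, task, iteration and
    attempt, within a validity window (unix timestamps)."""

    station_id: str
    task_id: str
    iteration: int
    issued_at: float
    expires_at: float
    attempt: int = 0

    def __post_init__(self):
        if self.iteration < 0:
            raise ClaimsError("iteration must be >= 0")
        if self.attempt < 0:
            raise ClaimsError("attempt must be >= 0")
        if self.expires_at <= self.issued_at:
            raise ClaimsError("expires_at must be after issued_at")


def generate_signing_key() -> bytes:
    """Fresh random 256-bit per-task key."""
    return secrets.token_bytes(32)


def _b64url(data: bytes) -> str:
    return base64.urlsafe_b64encode(data).rstrip(b"=").decode("ascii")


def _b64url_decode(segment: str) -> bytes:
    pad = "=" * (-len(segment) % 4)
    raw = base64.urlsafe_b64decode(segment + pad)
    # canonical-form check: tokens whose segments merely re-encode the same
    # bytes (e.g. trailing-bit tweaks) are not accepted either
    if _b64url(raw) != segment:
        raise ValueError("non-canonical base64url segment")
    return raw


def _signing_input(claims: TokenClaims) -> tuple[str, str]:
    header = _b64url(json.dumps({"alg": "HS256", "typ": "JWT"}, sort_keys=True).encode())
    payload = _b64url(
        json.dumps(
            {
                "station_id": claims.station_id,
                "task_id": claims.task_id,
                "iteration": claims.iteration,
                "attempt": claims.attempt,
                "iat": claims.issued_at,
                "exp": claims.expires_at,
            },
            sort_keys=True,
        ).encode()
    )
    return header, payload


def issue_iteration_token(claims: TokenClaims, signing_key: bytes) -> str:
    """Sign the claims into a compact JWT."""
    if not signing_key:
        raise ConfigurationError("missing signing key")
    header, payload = _signing_input(claims)
    mac = hmac.new(signing_key, f"{header}.{payload}".encode(), hashlib.sha256)
    return f"{header}.{payload}.{_b64url(mac.digest())}"


def _decode_unverified(token: str) -> tuple[str, str, str, dict]:
    parts = token.split(".")
    if len(parts) != 3:
        raise ForgedTokenError("malformed token: expected 3 segments")
    header_b64, payload_b64, sig_b64 = parts
    try:
        header = json.loads(_b64url_decode(header_b64))
        payload = json.loads(_b64url_decode(payload_b64))
    except Exception as exc:
        raise ForgedTokenError(f"malformed token segments: {exc}") from exc
    if not isinstance(header, dict) or header.get("alg") != "HS256":
        raise ForgedTokenError("unsupported or missing algorithm")
    if not isinstance(payload, dict):
        raise ForgedTokenError("malformed payload")
    return header_b64, payload_b64, sig_b64, payload


def validate_iteration_token(
    token: str,
    signing_key: bytes,
    expected_task: str,
    expected_iteration: int,
    known_stations: set[str] | frozenset[str],
    expected_attempt: int = 0,
    now: float | None = None,
) -> TokenClaims:
    """Return verified claims, or raise a typed rejection.

    Checks, in order: signature (forgery), claim completeness (forgery),
    station roster membership (integrity), task/iteration/attempt binding
    (replay), validity window with ±30 s clock-skew allowance (expiry).
    """
    header_b64, payload_b64, sig_b64, payload = _decode_unverified(token)
    mac = hmac.new(
        signing_key, f"{header_b64}.{payload_b64}".encode(), hashlib.sha256
    ).digest()
    try:
        presented = _b64url_decode(sig_b64)
    except Exception as exc:
        raise ForgedTokenError("undecodable signature") from exc
    if not hmac.compare_digest(mac, presented):
        raise ForgedTokenError("signature verification failed")
    try:
        claims = TokenClaims(
            station_id=str(payload["station_id"]),
            task_id=str(payload["task_id"]),
            iteration=int(payload["iteration"]),
            attempt=int(payload.get("attempt", 0)),
            issued_at=float(payload["iat"]),
            expires_at=float(payload["exp"]),
        )
    except (KeyError, TypeError, ValueError, ClaimsError) as exc:
        raise ForgedTokenError(f"invalid claims: {exc}") from exc
    if claims.station_id not in known_stations:
        raise UnknownStationError(
            f"station {claims.station_id!r} is not on the task roster"
        )
    if claims.task_id != expected_task:
        raise ReplayedTokenError(
            f"token bound to task {claims.task_id!r}, expected {expected_task!r}"
        )
    if claims.iteration != expected_iteration or claims.attempt != expected_attempt:
        raise ReplayedTokenError(
            f"token bound to iteration {claims.iteration} attempt {claims.attempt}; "
            f"current is iteration {expected_iteration} attempt {expected_attempt}"
        )
    t = time.time() if now is None else now
    if t > claims.expires_at + CLOCK_SKEW_S:
        raise ExpiredTokenError("token expired")
    if t < claims.issued_at - CLOCK_SKEW_S:
        raise ExpiredTokenError("token not yet valid")
    return claims
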