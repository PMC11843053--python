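"""Exception hierarchy shared across the federation components.

Token rejections form their own small tree so that the aggregation server
can refuse a request with a typed reason (forgery, replay, unknown station,
expiry) without leaking which check failed to the submitting party beyond
the category itself.
"""


class FedSegError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(FedSegError):
    """Invalid configuration value or inconsistent configuration."""


class DataError(FedSegError):
    """Problem with local training/validation data (missing, empty, malformed)."""


class FormatError(FedSegError):
    """Malformed on-disk artifact (weight container, NIfTI pair, config file)."""


class IntegrityError(FormatError):
    """Content digest mismatch: the artifact was corrupted or tampered with."""


class WeightCompatibilityError(FedSegError):
    """Weight manifests (entry names/shapes/order) do not match."""


# --- token rejections -------------------------------------------------------

class TokenRejection(FedSegError):
    """Base class: a station<->SAS exchange carried an unacceptable token."""


class ForgedTokenError(TokenRejection):
    """Signature verification failed or the token is not a well-formed JWT."""


class ReplayedTokenError(TokenRejection):
    """Claims are authentic but bound to a different task/iteration/attempt."""


class UnknownStationError(TokenRejection):
    """Token names a station that is not on the task roster."""


class ExpiredTokenError(TokenRejection):
    """Token presented outside its validity window."""


class ClaimsError(FedSegError):
    """Claims are internally inconsistent (e.g. expiry before issuance)."""


# --- coordinator ------------------------------------------------------------

class AuthenticationError(FedSegError):
    """Uniform failure for unknown entity or wrong password (anti-enumeration)."""


class AuthorizationError(FedSegError):
    """Authenticated entity lacks the role required for the operation."""


class ConflictError(FedSegError):
    """Duplicate registration, duplicate task, or second final-model store."""


class NotFoundError(FedSegError):
    """Unknown task or entity."""


class AccessDeniedError(FedSegError):
    """Operation exists but is denied in the current task state."""


class ChannelViolationError(FedSegError):
    """A payload arrived on a channel that must not carry it (weights on the
    status channel; image arrays on any channel)."""


class StateError(FedSegError):
    """Operation is invalid in the current lifecycle state (premature
    finalize, status regression, submission outside a waiting iteration)."""


class RetryLater(FedSegError):
    """Transient condition: the caller should retry after a backoff."""
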