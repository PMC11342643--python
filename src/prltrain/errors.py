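"""Exception hierarchy for the engine.

Everything raised deliberately by prltrain derives from :class:`PrlTrainError`
so callers (and the CLI) can catch engine errors in one clause.
"""

from __future__ import annotations


class PrlTrainError(Exception):
    """Base class for all engine errors."""


class ConfigError(PrlTrainError, ValueError):
    """Invalid configuration value or inconsistent parameters."""


class DomainError(PrlTrainError, ValueError):
    """Input outside the mathematical/physical domain of an operation."""


class PlacementError(PrlTrainError, ValueError):
    """A stimulus position falls outside the conceptual grid."""


class PermissionDeniedError(PrlTrainError):
    """The acting role is not allowed to perform the operation."""


class NotFoundError(PrlTrainError, KeyError):
    """A referenced entity (patient, result, practitioner) does not exist."""


class AbortedTestError(PrlTrainError):
    """A responder failed mid-test; carries the partial result so far."""

    def __init__(self, message: str, partial_result=None):
        super().__init__(message)
        self.partial_result = partial_result
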