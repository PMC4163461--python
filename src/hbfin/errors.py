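"""Exception hierarchy.

The CLI maps these onto distinct exit codes: configuration/parse problems
(:class:`ConfigError`) exit 2, data validation problems
(:class:`ValidationError`) exit 3, and inference failures
(:class:`InferenceError`) exit 4.
"""


class HBFINError(Exception):
    """Base class for all package errors."""


class ConfigError(HBFINError):
    """Malformed configuration, knowledge base, or serialized net."""


class FormulaSyntaxError(ConfigError):
    """A function formula failed to parse; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class NetBuildError(ConfigError):
    """The formula set cannot be assembled into a valid acyclic net."""


class ValidationError(HBFINError):
    """Input data violates a precondition or type invariant."""


class DomainError(ValidationError):
    """A numeric argument lies outside the operation's domain."""


class MissingAttributeError(ValidationError):
    """An anthropometric bound needs an attribute the record lacks."""


class FitError(ValidationError):
    """Membership-function fitting failed (too few samples, degenerate data)."""


class InferenceError(HBFINError):
    """Propagation failed on an inconsistent or unquantified net."""
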