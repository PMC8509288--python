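"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (parameter=2, data=3,
convergence=4) so scripted callers can tell a bad flag from a bad file.
"""


class AlbumagError(Exception):
    """Base class for all package errors."""


class ParameterError(AlbumagError, ValueError):
    """An argument or configuration field is invalid; the message names it."""


class DataError(AlbumagError, ValueError):
    """Input data is unusable (all-zero trace, non-finite values, ...)."""


class StateError(AlbumagError, RuntimeError):
    """An operation was applied to an object in the wrong state."""


class ConvergenceError(AlbumagError, RuntimeError):
    """A solver failed to converge and the caller asked for an exception."""
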