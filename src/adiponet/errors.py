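"""Exception hierarchy shared across the package."""


class AdiponetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AdiponetError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(AdiponetError, ValueError):
    """An input violates a documented precondition or invariant."""


class StateError(AdiponetError, ValueError):
    """An operation was applied to a matrix in the wrong processing stage."""


class ResourceError(AdiponetError, RuntimeError):
    """An enumeration or search exceeded its configured budget."""
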