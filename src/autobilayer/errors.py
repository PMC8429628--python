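"""Exception types shared across the package."""


class AutobilayerError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AutobilayerError, ValueError):
    """A parameter violates a documented precondition."""


class FormatError(AutobilayerError, ValueError):
    """A file could not be parsed as a supported trace/config format."""


class InsufficientDataError(AutobilayerError, ValueError):
    """Not enough observations to perform the requested computation."""


class NoEventsError(AutobilayerError, ValueError):
    """An operation that requires open dwells / events found none."""
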