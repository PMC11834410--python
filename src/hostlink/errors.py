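"""Exception hierarchy shared across the package."""


class HostlinkError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HostlinkError):
    """A file or table violates the expected format (names the offending cell)."""


class InvalidArgumentError(HostlinkError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(HostlinkError):
    """Input is structurally valid but degenerate (e.g. an all-zero sample)."""


class InfeasibleError(HostlinkError):
    """A resampling or matching design cannot be constructed from the data."""
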