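"""Exception hierarchy shared across the package.

Configuration problems and malformed data are kept distinct so the CLI can
map them onto different exit codes (2 and 1 respectively).
"""


class EmgConcordError(Exception):
    """Base class for all package errors."""


class ConfigError(EmgConcordError):
    """Invalid configuration or operation parameters."""


class DataFormatError(EmgConcordError):
    """Malformed or inconsistent input data (files, arrays)."""


class DegenerateInputError(EmgConcordError):
    """Input is structurally valid but degenerate (e.g. all-zero signal)."""


class ConcordanceUndefinedError(EmgConcordError):
    """A concordance cell has no usable window pairs left after exclusions."""
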