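"""Exception hierarchy shared across the package.

``DataError`` signals malformed or inconsistent input (CLI exit code 1),
``UsageError`` signals a misused interface (CLI exit code 2).
"""


class Peaks2FuncError(Exception):
    """Base class for all package-specific errors."""


class DataError(Peaks2FuncError):
    """Malformed, inconsistent or insufficient input data."""


class UsageError(Peaks2FuncError):
    """The interface was called in an unsupported way."""
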