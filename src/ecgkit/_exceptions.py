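"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 1, FormatError /
IOError -> 2, NumericalError -> 3.
"""


class EcgkitError(Exception):
    """Base class for all package errors."""


class ValidationError(EcgkitError, ValueError):
    """An input value violates a documented precondition."""


class FormatError(EcgkitError):
    """A file exists but does not parse as the declared format."""


class ConfigurationError(EcgkitError):
    """A model or pipeline configuration is internally inconsistent."""


class NumericalError(EcgkitError):
    """A computation produced non-finite values and cannot continue."""
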