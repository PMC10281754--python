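"""Exception hierarchy shared across the package."""


class DevqtlError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DevqtlError):
    """A file could not be parsed; message names the offending line."""


class DomainError(DevqtlError, ValueError):
    """An argument fell outside its documented domain."""


class InsufficientDataError(DevqtlError):
    """Too few observations to run the requested test or fit."""

    def __init__(self, message: str, **sizes: int):
        super().__init__(message)
        self.sizes = sizes


class NotEstimableError(DevqtlError):
    """Model cannot be estimated from the given design (e.g. monomorphic genotypes)."""


class UndefinedTestError(DevqtlError):
    """The test statistic is undefined for the given data (e.g. empty after zero removal)."""


class ConfigError(DevqtlError):
    """Pipeline configuration failed validation; message lists offending keys."""
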