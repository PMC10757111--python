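"""Exception hierarchy shared across the pipeline."""


class MMIthError(Exception):
    """Base class for all package errors."""


class FormatError(MMIthError):
    """A table or file does not conform to the expected dialect."""


class ValidationError(MMIthError):
    """A field value falls outside its allowed domain."""


class DomainError(MMIthError):
    """A computation was requested outside its mathematical domain."""


class InsufficientDataError(DomainError):
    """Too few observations to compute a statistic reliably."""

    def __init__(self, message: str, n: int = 0):
        super().__init__(message)
        self.n = n
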