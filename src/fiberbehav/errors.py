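"""Exception hierarchy shared by all pipeline stages."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """A file does not match the expected on-disk format (e.g. missing column)."""


class DataError(PipelineError):
    """A file parses but violates a data contract (e.g. non-monotone time)."""


class EmptyInputError(FormatError):
    """An input file contains no data rows."""


class PairingError(FormatError):
    """START/STOP point events cannot be paired into intervals."""


class ParameterError(PipelineError):
    """An operation was called with an out-of-contract parameter."""


class FitError(PipelineError):
    """A model fit failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}
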