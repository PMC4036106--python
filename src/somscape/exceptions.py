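"""Exception hierarchy shared by all pipeline stages."""


class SomscapeError(Exception):
    """Base class for all errors raised by this package."""


class InputFileError(SomscapeError):
    """A required input file is missing or unreadable."""


class MatrixParseError(SomscapeError):
    """A delimited matrix file is malformed (non-numeric cell, ragged rows)."""


class ValidationError(SomscapeError):
    """Arguments or in-memory data violate a documented contract."""


class OutputError(SomscapeError):
    """An output path cannot be written."""


class GenerationError(SomscapeError):
    """The synthetic-data generator could not satisfy its constraints."""
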