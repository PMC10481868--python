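"""Exception hierarchy shared across the pipeline stages."""


class GazeflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GazeflowError):
    """An on-disk artifact does not have the expected layout (e.g. missing column)."""


class DataError(GazeflowError):
    """An artifact parses but violates a data invariant (e.g. non-monotonic time)."""


class InsufficientDataError(GazeflowError):
    """A computation was requested on a stream too short/degenerate to support it."""


class ValidationError(GazeflowError):
    """A questionnaire or manifest record violates its value constraints."""


class ConfigError(GazeflowError):
    """A configuration is internally inconsistent or infeasible."""


class ModelError(GazeflowError):
    """A statistical model could not be fit."""
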