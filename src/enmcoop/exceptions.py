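"""Exception hierarchy for the pipeline.

Each error class maps to a distinct CLI exit code (see cli_report).
"""


class EnmCoopError(Exception):
    """Base class for all package errors."""


class InputError(EnmCoopError):
    """An input file is missing or unreadable."""


class FormatError(EnmCoopError):
    """A file's content cannot be parsed or written in the required format."""


class ConfigurationError(EnmCoopError):
    """Chain/subunit/parameter configuration is inconsistent with the input."""


class DisconnectedNetworkError(EnmCoopError):
    """The elastic network has more than one connected component.

    ``components`` holds node-index lists, largest first, so the offending
    fragments can be reported.
    """

    def __init__(self, message: str, components=None):
        super().__init__(message)
        self.components = components or []


class StageError(EnmCoopError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
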