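"""Exception hierarchy shared across the package."""


class GwsigError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GwsigError, ValueError):
    """A configuration or parameter combination is invalid."""


class ParseError(GwsigError, ValueError):
    """An input file could not be parsed or failed validation."""


class PipelineError(GwsigError, RuntimeError):
    """A pipeline stage failed.

    Carries the name of the failing stage so callers can report it.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
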