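"""Exception hierarchy shared across the package."""


class MMCSBError(Exception):
    """Base class for package-specific errors."""


class ConfigError(MMCSBError, ValueError):
    """A configuration object violates its invariants."""


class FormatError(MMCSBError, ValueError):
    """A file does not match the expected schema or format."""


class ChannelNotFoundError(MMCSBError, KeyError):
    """Requested signal channel is absent from an EDF file."""


class FitError(MMCSBError, RuntimeError):
    """A model cannot be fitted (e.g. single-class labels)."""


class StageError(MMCSBError, RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
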