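"""Exception hierarchy shared across the package."""


class EcgAnoiseError(Exception):
    """Base class for package errors."""


class ArgumentError(EcgAnoiseError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(EcgAnoiseError, ValueError):
    """Input is structurally valid but numerically degenerate (e.g. zero energy)."""


class FormatError(EcgAnoiseError, IOError):
    """A file or container does not conform to its declared format."""


class ChannelNotFoundError(EcgAnoiseError, KeyError):
    """Requested channel absent from a record."""

    def __init__(self, requested: str, available: list[str]):
        self.requested = requested
        self.available = list(available)
        super().__init__(
            f"channel {requested!r} not found; available channels: {self.available}"
        )


class TrainingDivergedError(EcgAnoiseError, RuntimeError):
    """Training produced a non-finite loss; carries the last good checkpoint."""

    def __init__(self, message: str, last_good_state=None):
        self.last_good_state = last_good_state
        super().__init__(message)
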