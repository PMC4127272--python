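"""Exception hierarchy for the codec.

Every stage raises a subclass of :class:`SbpnError` so callers (and the CLI)
can distinguish codec failures from programming errors.
"""


class SbpnError(Exception):
    """Base class for all codec errors."""


class UnsupportedFormatError(SbpnError):
    """Image file exists but is not an 8-bit grayscale-convertible raster."""


class CorruptContainerError(SbpnError):
    """The .sbpn container is malformed (bad magic, version, or truncation).

    Parameters
    ----------
    message : str
    offset : int
        Byte offset at which parsing failed.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)


class CorruptStreamError(SbpnError):
    """A coded coefficient stream is internally inconsistent."""


class ScaleError(SbpnError):
    """Normalization scale too small: a value left the [-1, 1] range."""


class TrainingError(SbpnError):
    """Network training diverged (NaN/Inf error)."""

    def __init__(self, message: str, epoch: int | None = None):
        self.epoch = epoch
        if epoch is not None:
            message = f"{message} (epoch {epoch})"
        super().__init__(message)


class StageError(SbpnError):
    """Wraps an error with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
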