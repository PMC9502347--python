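"""Exception hierarchy."""


class DermaquantError(Exception):
    """Base class for all package errors."""


class ParameterError(DermaquantError, ValueError):
    """Invalid generator, measurement or configuration parameter."""


class SurfaceNotFoundError(DermaquantError):
    """No column of the image crossed the background threshold."""


class InsufficientLinesError(DermaquantError):
    """Fewer usable columns than requested SCT measurement lines."""

    def __init__(self, usable: int, requested: int):
        self.usable = usable
        self.requested = requested
        super().__init__(
            f"only {usable} usable columns for {requested} requested SCT lines"
        )


class ThresholdError(DermaquantError):
    """Threshold could not be computed (empty control set, constant image)."""


class DatasetError(DermaquantError):
    """Dataset generation or I/O problem."""


class ManifestError(DermaquantError):
    """Study manifest inconsistent with the data it describes."""


class StatsError(DermaquantError):
    """Statistical test preconditions violated."""
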