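"""Exception hierarchy shared across the pipeline.

Stage-level signals subclass :class:`TensileDicError` so the pipeline runner
can attach them to a specimen and keep going; only programming errors escape.
"""


class TensileDicError(Exception):
    """Base class for all package-specific signals."""


class InvalidArgumentError(TensileDicError, ValueError):
    """An argument violates a documented precondition."""


class OutOfRangeError(TensileDicError, ValueError):
    """A query time or index lies outside the supported span."""


class DegenerateSubsetError(TensileDicError):
    """A subset has (near-)zero intensity variance and cannot be correlated."""


class TrackingLostError(TensileDicError):
    """Every subset fell below the correlation threshold in one frame."""

    def __init__(self, frame_index: int):
        self.frame_index = frame_index
        super().__init__(f"all subsets invalid at frame {frame_index}")


class MeasurementGapError(TensileDicError):
    """No valid subset near an extensometer anchor; the series carries a gap."""


class NoFractureError(TensileDicError):
    """The stress-strain curve ended before a qualifying stress drop."""


class SchemaError(TensileDicError):
    """An input table is missing a required column."""


class DataError(TensileDicError):
    """An input table is structurally present but semantically invalid."""
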