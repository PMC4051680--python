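"""Exception hierarchy shared across the package."""


class PlastidtxError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PlastidtxError):
    """An on-disk input could not be parsed; message names the offending line/row."""


class ConfigError(PlastidtxError):
    """A run configuration is invalid (missing file, parameter out of range)."""


class StageError(PlastidtxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


class DegenerateSampleError(PlastidtxError):
    """A statistical test received a degenerate sample (n < 2 or zero variance)."""


class DegenerateGroupingError(PlastidtxError):
    """A group comparison received an empty group."""


class UnclassifiableSegmentError(PlastidtxError):
    """A transcribed segment fits none of the ncRNA subtype rules."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class PlacementError(PlastidtxError):
    """The simulator could not place a planted feature under its constraints."""
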