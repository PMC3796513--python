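"""Exception hierarchy for the bilateral-limb PET pipeline.

Every stage raises a subclass of :class:`LimbPetError`, so callers can
distinguish a malformed input file from a degenerate reference region or a
failed segmentation, and the pipeline can attach stage identity when it
re-raises.
"""


class LimbPetError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(LimbPetError):
    """A volume file is not a recognisable Analyze 7.5 pair."""


class TruncationError(FormatError):
    """The image file is shorter or longer than the header declares."""


class InvariantError(LimbPetError, ValueError):
    """A domain object violates one of its structural invariants."""


class SegmentationError(LimbPetError):
    """Fewer than two limb-sized components found, or a seed fell outside."""


class DegenerateReferenceError(LimbPetError):
    """Reference region has zero variance or fewer than two voxels."""


class DegenerateStatisticsError(LimbPetError):
    """A statistical test is undefined for the given samples."""


class PipelineError(LimbPetError):
    """Wraps a stage failure with the identity of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
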