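"""Exception hierarchy shared across the pipeline."""


class SomatrackError(Exception):
    """Base class for all somatrack errors."""


class SequenceFormatError(SomatrackError):
    """Image file does not match the declared 5D layout."""


class ChannelCountError(SequenceFormatError):
    """The channel axis does not hold exactly two channels."""


class UnrecoverableSequenceError(SomatrackError):
    """Every frame of a sequence is corrupted; repair impossible."""


class InsufficientPlanesError(SomatrackError):
    """Too few axial planes for cubic-spline interpolation."""


class UnmeasurableProfileError(SomatrackError):
    """No half-maximum crossing in any sampled intensity profile."""


class GMMDegenerateError(SomatrackError):
    """Two-component intensity mixture collapsed onto one mode."""


class EmptyFrameError(SomatrackError):
    """A frame holds no detections where at least one is required."""


class DegenerateGeometryError(SomatrackError):
    """Point configuration too flat to determine a 3D similarity."""


class DegenerateTemplateError(SomatrackError):
    """Template image yields an empty foreground mask."""


class InfeasiblePlacementError(SomatrackError):
    """More nuclei requested than foreground voxels available."""


class AnnotationParseError(SomatrackError):
    """Malformed annotation file."""


class UndefinedScoreError(SomatrackError):
    """Score requested on all-zero match counts."""


class AlignmentImpossibleError(SomatrackError):
    """Batch reference distribution has a zero 99th percentile."""


class PipelineStageError(SomatrackError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
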