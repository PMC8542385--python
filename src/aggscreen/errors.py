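"""Exception hierarchy for the aggscreen pipeline.

Every stage raises a subclass of :class:`AggScreenError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class AggScreenError(Exception):
    """Base class for all aggscreen errors."""


class GenerationError(AggScreenError):
    """Synthetic-image generation failed (e.g. placement density too high)."""


class ImageReadError(AggScreenError):
    """An input image file could not be read or mapped to channels."""


class SegmentationError(AggScreenError):
    """Nuclei segmentation / region tessellation failed."""


class DetectionError(AggScreenError):
    """Aggregate calling failed (e.g. nothing to call)."""


class ScreenError(AggScreenError):
    """Plate-level analysis failed (layout, baseline, controls)."""


class FragmentError(AggScreenError):
    """Dish/fragment analysis failed."""


class PipelineStageError(AggScreenError):
    """An analyze_field stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
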