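"""Exception types shared across the pipeline stages."""


class MealDepthError(Exception):
    """Base class for all package errors."""


class InvalidDepthError(MealDepthError):
    """A depth value violated a precondition (e.g. non-positive, or 0 inside an ROI)."""


class DegenerateRegionError(MealDepthError):
    """A mask region is empty or collinear and has no usable geometry."""


class NonInvertibleError(MealDepthError):
    """A point configuration yields a singular homography system."""


class DimensionMismatchError(MealDepthError):
    """Paired images/masks/intrinsics disagree on image dimensions."""


class PipelineError(MealDepthError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
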