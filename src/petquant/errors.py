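"""Package exception hierarchy."""


class PetquantError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PetquantError, ValueError):
    """Raised when an argument violates a documented precondition."""


class GeometryError(PetquantError, ValueError):
    """Raised when volumes, masks or VOIs are geometrically inconsistent."""


class EmptyVOIError(GeometryError):
    """Raised when a VOI contains no voxel centers."""


class UnderDeterminedError(InvalidInputError):
    """Raised when a fit has fewer data points than free parameters."""


class PipelineError(PetquantError, RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
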