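"""Exception hierarchy for the measurement pipeline."""


class BovimetryError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BovimetryError):
    """Invalid configuration value or unknown configuration key."""


class EmptyCloudError(BovimetryError):
    """An operation received or produced a cloud with no finite points."""


class ParameterError(BovimetryError):
    """An operation parameter violates its precondition."""


class DegenerateModelError(BovimetryError):
    """Geometric model fitting failed (e.g. collinear points for a plane)."""


class DegeneratePoseError(BovimetryError):
    """Pose normalization or orientation correction cannot proceed."""


class SegmentationError(BovimetryError):
    """Subject isolation produced no usable cluster."""


class ImpossibleSurfaceTypeError(BovimetryError):
    """The (H ~ 0, K > 0) curvature-sign combination, which no real surface attains."""


class TrainingError(BovimetryError):
    """Classifier training diverged or was misconfigured."""


class BoostingStoppedError(BovimetryError):
    """Instance-transfer boosting halted: target error rate reached 0.5."""


class DescriptorError(BovimetryError):
    """A local descriptor could not be computed (too few neighbors)."""


class DatabaseError(BovimetryError):
    """Feature-model database is incomplete or malformed."""


class LandmarkNotFoundError(BovimetryError):
    """No candidate matched the feature database within the threshold."""


class NotCattleError(BovimetryError):
    """The classifier gate rejected the segmented subject."""


class AuxiliaryPointError(BovimetryError):
    """A derived auxiliary point could not be constructed."""


class PipelineError(BovimetryError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
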