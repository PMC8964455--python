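"""Exception hierarchy for the penaltypose package."""


class PenaltyPoseError(Exception):
    """Base class for all package-specific errors."""


class KeypointFormatError(PenaltyPoseError, ValueError):
    """Malformed keypoint input (wrong landmark count, unparseable record)."""


class FrameResolutionError(PenaltyPoseError, LookupError):
    """No frame with the required landmarks inside the search window."""


class RoleAssignmentError(PenaltyPoseError, ValueError):
    """Kicker/goalkeeper roles cannot be assigned (e.g. fewer than 2 persons)."""


class GeometryError(PenaltyPoseError, ValueError):
    """Degenerate correspondence configuration or singular homography."""


class PointAtInfinityError(GeometryError):
    """Projection of a point whose homogeneous weight vanishes."""


class DegeneratePairError(PenaltyPoseError, ValueError):
    """A left-right landmark pair (or a body-axis segment) is degenerate."""


class SchemaError(PenaltyPoseError, ValueError):
    """Tabular input violates the expected schema (columns, duplicate keys)."""


class LevelValidationError(PenaltyPoseError, ValueError):
    """A coded value is outside the legal level set of its variable."""


class MergeError(PenaltyPoseError, ValueError):
    """Feature tables share no penalty identifiers."""


class DegenerateTableError(PenaltyPoseError, ValueError):
    """Contingency table with an empty margin."""


class UndefinedCorrelationError(PenaltyPoseError, ValueError):
    """Correlation requested on a constant (zero-variance) input."""


class ModelFitError(PenaltyPoseError, ValueError):
    """Logistic model cannot be fitted (e.g. single-class labels)."""


class ConfigError(PenaltyPoseError, ValueError):
    """Invalid simulation or pipeline configuration."""


class PipelineStageError(PenaltyPoseError, RuntimeError):
    """A pipeline stage failed; carries the stage name in the message."""
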