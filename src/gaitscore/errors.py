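"""Exception hierarchy.

Every error raised by the package derives from :class:`GaitScoreError`;
the CLI maps each category to a distinct exit code.
"""


class GaitScoreError(Exception):
    """Base class for all gaitscore errors."""

    exit_code = 1


class FormatError(GaitScoreError):
    """A file does not have the expected layout (missing column, bad header)."""

    exit_code = 2


class DataError(GaitScoreError):
    """A file parses but its content violates a data invariant."""

    exit_code = 3


class ModelError(GaitScoreError):
    """Scorer parameters violate the model constraint set."""

    exit_code = 4


class SegmentationError(GaitScoreError):
    """Gait events could not be detected or do not interleave."""

    exit_code = 5


class InsufficientDataError(GaitScoreError):
    """Too few steps / subjects / levels for the requested operation."""

    exit_code = 6


class CalibrationError(GaitScoreError):
    """Sensor-frame correction failed (gravity unobservable)."""

    exit_code = 7


class KinematicsError(GaitScoreError):
    """Trajectory integration failed (e.g. no zero-velocity instant)."""

    exit_code = 8


class FeatureError(GaitScoreError):
    """A gait feature could not be computed from a cycle."""

    exit_code = 9


class FitError(GaitScoreError):
    """Constrained optimisation failed; carries the last feasible iterate."""

    exit_code = 10

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params
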