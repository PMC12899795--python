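"""Exception hierarchy for the trunk-IMU gait pipeline.

Every rejection named in a module contract maps to a distinct class so
callers (and the CLI) can report the stage and cause without string
matching.
"""


class GaitError(Exception):
    """Base class for all trunkgait errors."""


class SchemaError(GaitError, ValueError):
    """A delimited recording file is missing required channel columns."""


class NonUniformRateError(GaitError, ValueError):
    """Timestamps deviate from a uniform sampling grid beyond tolerance."""


class SensorRangeError(GaitError, ValueError):
    """Simulated signal exceeds the sensor's dynamic range (±8 g, ±1000 deg/s)."""


class InsufficientDataError(GaitError, ValueError):
    """Fewer strides/steps/samples available than an operation requires."""


class GravityReferenceError(GaitError, ValueError):
    """Mean acceleration magnitude too far from 1 g to serve as a tilt reference."""


class DegenerateSignalError(GaitError, ValueError):
    """Zero-variance or otherwise degenerate input where structure is required."""


class PeakSearchError(GaitError, ValueError):
    """No qualifying autocorrelation extremum in the requested lag window."""


class RankDeficiencyError(GaitError, ValueError):
    """Regression design matrix is rank deficient (names the collinear term)."""


class ConvergenceError(GaitError, RuntimeError):
    """A mixed-model fit failed to converge."""


class StageError(GaitError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the causal error."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
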