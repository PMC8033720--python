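"""Exception hierarchy for ptosiskit.

Every stage of the pipeline raises a subclass of :class:`PtosisKitError`,
so callers (and the CLI) can catch one type and tag the failing stage.
"""


class PtosisKitError(Exception):
    """Base class for all ptosiskit errors."""


class ConfigurationError(PtosisKitError):
    """Invalid configuration values (proportions, scales, grids...)."""


class MeshFormatError(PtosisKitError):
    """Malformed Wavefront OBJ input."""


class GeometryError(PtosisKitError):
    """Degenerate geometry or points outside the fitted surface region."""


class CalibrationError(PtosisKitError):
    """Unusable fiducial-disc measurements."""


class MeasurementError(PtosisKitError):
    """Missing or inconsistent landmark annotations."""


class DataError(PtosisKitError):
    """Record assembly problems (duplicate ids, schema mismatch)."""


class SplitError(PtosisKitError):
    """Train/test partition cannot satisfy its constraints."""


class BalanceError(PtosisKitError):
    """Training-set balancing applied to non-binary labels."""


class FitError(PtosisKitError):
    """Model fitting received unusable input."""


class PredictError(PtosisKitError):
    """Prediction input does not match the trained model."""


class EvaluationError(PtosisKitError):
    """Metric computation on degenerate input."""
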