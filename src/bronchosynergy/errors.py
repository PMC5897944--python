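"""Exception hierarchy for study-data validation and analysis failures."""


class StudyDataError(ValueError):
    """Base class for all data / analysis errors raised by this package."""


class SchemaError(StudyDataError):
    """Input table does not conform to the required column schema."""


class RowValidationError(StudyDataError):
    """A row violates a field-level constraint (e.g. non-positive concentration)."""


class DuplicateRowError(StudyDataError):
    """Duplicate (tissue, arm, concentration) entry in an input table."""


class DegenerateTissueError(StudyDataError):
    """Tissue has no usable dynamic range (plateau equals papaverine reference)."""


class QCFieldMissingError(StudyDataError):
    """A vitality QC field required for the tissue's compartment is absent."""


class InsufficientDataError(StudyDataError):
    """Too few points to fit the requested model."""


class InsufficientReplicationError(StudyDataError):
    """Fewer than the minimum number of tissues in an analysis arm."""


class FitFailureError(StudyDataError):
    """Nonlinear fit failed to converge from every start; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NotBellShapedError(StudyDataError):
    """Curve is monotone; the bell-shape fitter redirects to the sigmoid path."""


class DegenerateCurveError(StudyDataError):
    """All fractional effects sit at a clipping bound; no median-effect fit possible."""


class DomainError(StudyDataError):
    """Argument outside the mathematical domain of the operation."""


class ConfigurationError(StudyDataError):
    """Inconsistent or incomplete analysis configuration."""


class PairingError(StudyDataError):
    """Dataset and ground truth do not belong to the same simulation."""
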