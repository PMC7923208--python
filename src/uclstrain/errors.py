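"""Exception hierarchy.

Every error carries an ``exit_code`` so the command-line layer can map any
failure to a distinct, stable process exit status.
"""


class UclStrainError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParseError(UclStrainError):
    """A landmark file could not be parsed (malformed CSV/JSON)."""

    exit_code = 2


class SchemaViolationError(UclStrainError):
    """A landmark file parsed but violates the landmark schema."""

    exit_code = 3


class MissingLandmarkError(UclStrainError):
    """A required landmark is absent from a specimen."""

    exit_code = 4

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing required landmark: {field!r}")


class InsufficientPointsError(UclStrainError):
    """Too few points for a sphere fit (fewer than 4)."""

    exit_code = 5


class DegenerateConfigurationError(UclStrainError):
    """Sphere-fit points are coplanar/collinear within tolerance."""

    exit_code = 6


class DegeneratePlaneError(UclStrainError):
    """Frame landmarks are collinear; no epicondylar plane exists."""

    exit_code = 7


class NonUnitAxisError(UclStrainError):
    """A rotation axis direction does not have unit norm."""

    exit_code = 8


class NonpositiveReferenceLengthError(UclStrainError):
    """Strain is undefined for a non-positive reference length."""

    exit_code = 9


class MissingReferencePoseError(UclStrainError):
    """The pose grid does not contain the 90° flexion / 0° valgus reference."""

    exit_code = 10


class IncompleteTableError(UclStrainError):
    """A strain table is missing fiber x pose cells."""

    exit_code = 11


class InvalidParamsError(UclStrainError):
    """Synthetic-generator parameters are out of range."""

    exit_code = 12
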