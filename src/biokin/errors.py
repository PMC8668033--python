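"""Exception hierarchy and warning categories."""


class BiokinError(Exception):
    """Base class for all biokin errors."""


class InvalidCalibrationError(BiokinError):
    """Calibration diameters are nonpositive or non-finite."""


class IncompleteFrameError(BiokinError):
    """A frame does not supply exactly landmark points 1, 2 and 3."""


class DegenerateBaselineError(BiokinError):
    """The two baseline landmarks coincide; no segment frame can be fixed."""


class InvalidDirectionError(BiokinError):
    """A zero direction vector was supplied for an endplate."""


class ZeroArcError(BiokinError):
    """Inclination and reclination global angles coincide; no movement arc."""


class IncompleteLevelError(BiokinError):
    """A requested level is missing from one or more frames."""


class IncompleteCurveError(BiokinError):
    """Fewer than two frames; a motion curve needs at least two samples."""


class InsufficientKnotsError(BiokinError):
    """Fewer than three knots; the 3-pose exam is the interpolation minimum."""


class InsufficientFamilyError(BiokinError):
    """Fewer than three curves supplied to build a motion surface."""


class MissingPoseError(BiokinError):
    """An endpoint pose (inclination or reclination) is absent from the exam."""


class MissingUpperPlateError(BiokinError):
    """No upper endplate is available for the conventional angle at this level."""


class EmptyCurveError(BiokinError):
    """A motion curve with no samples cannot carry a signature."""


class IncompleteSectionError(BiokinError):
    """Not all levels of the spine section are present."""


class DuplicateLevelError(BiokinError):
    """The same level appears more than once in a signature series."""


class IncompatibleSignatureError(BiokinError):
    """Signatures from different sections or level sets cannot be compared."""


class InsufficientCohortError(BiokinError):
    """Fewer subjects than the analysis requires."""


class ReferenceGapError(BiokinError):
    """The reference surrogate lacks a level present in the patient exam."""


class NoCandidateError(BiokinError):
    """Every level was excluded from the best-segment search."""


class DegenerateSubstitutionError(BiokinError):
    """Worst and best segment coincide; substitution is undefined."""


class InvalidHeightError(BiokinError):
    """A disc or device height is nonpositive or non-finite."""


class EmptyGridError(BiokinError):
    """The device height grid is empty."""


class LevelMismatchError(BiokinError):
    """Two curves that must share a level do not."""


class SchemaError(BiokinError):
    """An input table or record does not match the defined schema."""


class ConfigError(BiokinError):
    """A configuration object violates its invariants."""


class DegenerateTriangleWarning(UserWarning):
    """Collinear landmarks: the triangle area is zero in this frame."""


class OutOfRangeFractionWarning(UserWarning):
    """An intermediate frame lies outside the inclination-reclination arc."""
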