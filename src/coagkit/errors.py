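"""Exception hierarchy for coagkit.

Every error raised deliberately by the package derives from
:class:`CoagKitError`, so callers can catch one type at the pipeline
boundary while still discriminating the specific failure.
"""


class CoagKitError(Exception):
    """Base class for all coagkit errors."""


class RecipeError(CoagKitError):
    """Invalid reaction composition (non-positive volume, overfull cuvette)."""


class MeasurementError(CoagKitError):
    """Invalid raw measurement (e.g. non-positive clotting time)."""


class CurveValidationError(CoagKitError):
    """A concentration curve violates its structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class InsufficientPointsError(CoagKitError):
    """Too few distinct concentrations (or samples) for the operation."""


class UndefinedShiftError(CoagKitError):
    """Fold-shift requested against a non-positive reference value."""


class IncompatibleCurvesError(CoagKitError):
    """Paired curves differ in concentration grid or replicate count."""


class IncompletePlateError(CoagKitError):
    """A fluorescence plate is missing a required well role."""


class GridMismatchError(CoagKitError):
    """Time grids of traces that must align do not."""


class InvalidControlError(CoagKitError):
    """A no-venom control measurement is unusable (non-positive time)."""


class InsufficientDataError(CoagKitError):
    """A trace or replicate set is too short for the requested operation."""


class ParseError(CoagKitError):
    """A delimited-text input failed to parse.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message, line=None, path=None):
        self.line = line
        self.path = path
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class ConfigError(CoagKitError):
    """Study configuration is missing keys or references absent paths."""
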