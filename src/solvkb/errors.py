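"""Exception hierarchy shared across the package."""


class SolvKBError(Exception):
    """Base class for all package errors."""


class ParseError(SolvKBError):
    """A structure or table file could not be parsed.

    Carries the 1-based line number at which parsing failed when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(SolvKBError):
    """An input contained no usable records/frames."""


class EmptySpeciesError(SolvKBError):
    """A solvent species has zero molecules."""


class ConfigurationError(SolvKBError):
    """A run or file configuration is invalid or incomplete."""


class UnsupportedFeatureError(SolvKBError):
    """Input requests a feature outside this package's scope (e.g. triclinic boxes)."""


class IncompatibilityError(SolvKBError):
    """Two results that must share a grid/species/temperature do not."""


class PartitionError(SolvKBError):
    """A solute-atom partition does not cover all atoms."""


class InvalidDensityError(SolvKBError):
    """A number density is non-positive where a positive one is required."""
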