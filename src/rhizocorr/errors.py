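"""Exception hierarchy shared across the package."""


class RhizocorrError(Exception):
    """Base class for all package errors."""


class SchemaError(RhizocorrError):
    """Input table is missing a required column."""


class ParseError(RhizocorrError):
    """A cell could not be parsed (non-integer / negative count); names the row."""


class ValidationError(RhizocorrError):
    """Records violate a data-model invariant (duplicate keys, nodulated controls)."""


class UnbalancedDesignError(RhizocorrError):
    """A computation that requires a balanced design was given unequal cells."""

    def __init__(self, message, offending_cells=()):
        super().__init__(message)
        self.offending_cells = list(offending_cells)


class ParameterError(RhizocorrError):
    """Invalid simulation parameters (non-symmetric / non-PSD covariance, bad dims)."""


class DegenerateDesignError(RhizocorrError):
    """g < 2 or k < 2: one of the covariance components is inestimable."""


class DegenerateAnovaError(RhizocorrError):
    """Zero error degrees of freedom or constant response: F is undefined."""


class TransformDomainError(RhizocorrError):
    """ln transform requested on a zero count under the strict policy."""


class InsufficientDataError(RhizocorrError):
    """Too few observations in a contrast group or jackknife."""


class DegenerateFitError(RhizocorrError):
    """Major-axis fit is undefined (identical points, eigenvalue tie, vertical axis)."""


class OverwriteError(RhizocorrError):
    """Refusing to overwrite an existing output file without force."""
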