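"""Exception hierarchy shared across the package.

Every error raised by cytovax derives from :class:`CytovaxError`, so callers
can catch the package's failures without catching unrelated bugs.
"""


class CytovaxError(Exception):
    """Base class for all cytovax errors."""


class SchemaError(CytovaxError):
    """An input table is missing a required column or has a malformed header."""


class ReferentialError(CytovaxError):
    """A record references a patient that does not exist."""


class ValidationError(CytovaxError):
    """A record violates a stated field invariant (range, sign, date order)."""


class MissingDataError(CytovaxError):
    """A required measurement (sample x cytokine, baseline) is absent."""


class DegenerateInputError(CytovaxError):
    """Input has no usable variation (all zeros, no events, empty stratum)."""


class SmallSampleError(CytovaxError):
    """Too few observations for the requested test."""


class ParameterError(CytovaxError):
    """A caller-supplied parameter is out of its valid range."""


class SpecError(CytovaxError):
    """A simulation spec is internally inconsistent."""


class FitError(CytovaxError):
    """A model fit failed to converge or the design is rank deficient."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class SaturationError(CytovaxError):
    """An assay signal lies at or beyond the high asymptote of the curve."""


class BelowRangeError(CytovaxError):
    """An assay signal lies at or below the zero-dose asymptote."""


class SeparationError(FitError):
    """Logistic fit diverged: covariates perfectly separate the classes."""


class StageError(CytovaxError):
    """A pipeline stage failed; carries the stage name and original cause."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
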