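"""Exception hierarchy shared across the package."""


class BProundError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BProundError, ValueError):
    """A configuration object failed validation; the message names the field."""


class InputError(BProundError, ValueError):
    """An operation received an out-of-range or mistyped input."""


class EmptyInputError(InputError):
    """An operation that requires data received an empty table or subset."""


class SchemaError(BProundError, ValueError):
    """A table is missing required columns or holds invalid codes."""


class FitError(BProundError, RuntimeError):
    """Model fitting failed (non-convergence, separation, ...)."""


class DegenerateFitError(FitError):
    """The data cannot support a fit at all (e.g. no events)."""


class UndefinedScalingError(BProundError, ZeroDivisionError):
    """Whole-cohort generalization requested with a zero experimental rounding fraction."""
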