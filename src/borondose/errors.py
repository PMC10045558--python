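"""Exception hierarchy shared across the package.

Validation failures (bad user input) and configuration failures (missing
calibration data) are kept distinct so the command line layer can map them
to different exit codes.
"""


class BoronDoseError(Exception):
    """Base class for all package errors."""


class InputValidationError(BoronDoseError, ValueError):
    """A caller supplied a value outside the documented domain."""


class ConfigurationError(BoronDoseError):
    """A beam/factor configuration is incomplete (e.g. missing kerma entry)."""


class UnknownFactorError(ConfigurationError):
    """No CBE factor is known for the requested carrier/tissue pair.

    Mirrors the convention of leaving report cells blank when a compound's
    biological effectiveness in a tissue has never been measured.
    """


class InconsistentInputsError(InputValidationError):
    """Inputs are jointly impossible (e.g. a negative dose component implied)."""


class InsufficientDataError(BoronDoseError):
    """Too few observations to run the requested estimator."""


class DegenerateFitError(BoronDoseError):
    """The data admit no informative fit (e.g. all survival fractions are 1)."""


class UndefinedSFError(BoronDoseError):
    """A survival fraction is undefined (zero control plating efficiency...)."""


class UndefinedResultError(BoronDoseError):
    """A summary quantity is undefined for these data (e.g. KM median)."""


class SchemaError(BoronDoseError):
    """A tabular input violated its declared schema."""

    def __init__(self, message, errors=None):
        super().__init__(message)
        self.errors = list(errors or [])
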