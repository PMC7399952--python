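"""Exception hierarchy for meddsurvey.

All package errors derive from :class:`MedDSurveyError` so callers can catch
one base class; subclasses mark which contract was violated.
"""


class MedDSurveyError(Exception):
    """Base class for all meddsurvey errors."""


class ConfigurationError(MedDSurveyError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(MedDSurveyError):
    """An input table is missing a mandatory column."""


class ValidationError(MedDSurveyError):
    """A value violates a domain invariant (e.g. negative intake)."""


class DegenerateScaleError(MedDSurveyError):
    """Robust scale (MAD) is zero, so modified z-scores are undefined."""


class DegenerateStratumError(MedDSurveyError):
    """An education stratum is too small or has zero variance to standardize."""


class LonelyPSUError(MedDSurveyError):
    """A stratum contains a single PSU and the lonely-PSU policy is 'error'."""


class ConvergenceError(MedDSurveyError):
    """Iteratively reweighted least squares failed to converge."""


class SeparationError(MedDSurveyError):
    """Complete separation detected in a logistic fit."""
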