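"""Exception and warning hierarchy.

Exit-code mapping used by the CLI: :class:`ValidationError` (and subclasses)
exit with 1, :class:`ConfigurationError` with 2.
"""


class XlossError(Exception):
    """Base class for all package errors."""


class ValidationError(XlossError):
    """Invalid input data (bad counts, broken invariants, malformed rows)."""


class ParameterError(ValidationError):
    """Model parameters outside their admissible domain."""


class UndefinedRateError(ValidationError):
    """A rate or proportion with a zero denominator."""


class DegenerateModelError(ValidationError):
    """Model configuration with zero total survival mass."""


class InconsistentCountsError(ValidationError):
    """Observed counts incompatible with any valid parameter point."""


class SchemaError(ValidationError):
    """Table file missing required columns."""


class ConfigurationError(XlossError):
    """Bad run configuration (unknown labels, infeasible options)."""


class SmallExpectedCountWarning(UserWarning):
    """A chi-square table has an expected cell below 5."""


class NegativeExcessWarning(UserWarning):
    """More XXY daughters than X0 sons; signed excess reported anyway."""


class BoundaryFitWarning(UserWarning):
    """A maximum-likelihood estimate was clamped to the parameter boundary."""
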