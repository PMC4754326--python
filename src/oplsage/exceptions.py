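"""Exception hierarchy used across the package."""


class OplsAgeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(OplsAgeError):
    """A table or matrix does not conform to the expected column schema."""


class ParseError(OplsAgeError):
    """A delimited-text cell could not be parsed; carries row/column context."""


class ValidationError(OplsAgeError):
    """A domain object violates one of its invariants."""


class DegenerateFeatureError(OplsAgeError):
    """A feature column has zero variance and cannot be unit-variance scaled."""


class DegenerateDataError(OplsAgeError):
    """Input data lacks the variation required by an estimator (e.g. constant age)."""


class RankError(OplsAgeError):
    """Requested model complexity exceeds what the data's rank supports."""
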