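"""Exception hierarchy for the glycemic-response pipeline."""


class GlyloadError(Exception):
    """Base class for all package errors."""


class ConfigError(GlyloadError, ValueError):
    """Invalid simulation or pipeline configuration."""


class InputError(GlyloadError, ValueError):
    """A record or curve is missing a required field or value."""


class SchemaError(GlyloadError, ValueError):
    """A CSV/YAML file does not match the expected schema."""


class MissingReferenceError(GlyloadError, LookupError):
    """No sugar-reference curve exists for a (participant, tier) pair."""


class DegenerateReferenceError(GlyloadError, ValueError):
    """Reference iAUC is zero or negative; GI is undefined."""


class JoinError(GlyloadError, KeyError):
    """A record references a meal_id absent from the meal table."""


class SingularDesignError(GlyloadError, ValueError):
    """The regression design matrix is rank-deficient."""


class DegenerateRegressionError(GlyloadError, ValueError):
    """The regressor has zero variance; the slope is unidentified."""


class InsufficientDataError(GlyloadError, ValueError):
    """Too few observations for the requested fit or summary."""
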