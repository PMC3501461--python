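"""Exception types shared across the survey pipeline."""


class SurveyError(Exception):
    """Base class for all mcsurvey errors."""


class ValidationError(SurveyError):
    """An input record or file violates a documented invariant."""


class EmptyInputError(ValidationError):
    """An input file contains no usable records."""


class ConfigError(SurveyError):
    """A configuration value is missing, unknown, or out of range."""
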