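"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the offending field."""


class FormatError(ValueError):
    """An input file does not match the expected schema."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries the row number."""


class UndefinedDenominatorError(ZeroDivisionError):
    """A rate was requested with an expected-report count of zero."""


class NoVariationError(ValueError):
    """A rank test was requested on data with no variation (all differences zero)."""
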