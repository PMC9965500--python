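"""Exception hierarchy for the aisac package."""


class AisacError(Exception):
    """Base class for all errors raised by aisac."""


class ParseError(AisacError):
    """A dataset file could not be parsed (malformed CSV/ARFF)."""


class ValidationError(AisacError):
    """Input data violates a structural contract (schema, labels, shapes)."""


class ConfigurationError(AisacError):
    """A parameter or option is outside its admissible domain."""
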