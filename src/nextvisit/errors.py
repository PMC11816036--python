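"""Exception hierarchy."""


class NextVisitError(Exception):
    """Base class for package errors."""


class ConfigurationError(NextVisitError, ValueError):
    """Invalid configuration value or combination."""


class CensoringError(NextVisitError, ValueError):
    """A target code appeared inside a patient's censored input window."""


class VocabularyError(NextVisitError, KeyError):
    """Unknown or duplicate code during vocabulary operations."""


class SchemaError(NextVisitError, ValueError):
    """Malformed serialized cohort or config file."""


class SamplingError(NextVisitError, ValueError):
    """A few-shot sampling policy cannot be satisfied by the available split."""
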