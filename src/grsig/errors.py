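"""Exception types shared across the pipeline."""


class GrsigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GrsigError):
    """A simulation or analysis configuration violates its invariants."""


class DataError(GrsigError):
    """Input data violate a precondition of an operation."""
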