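"""Exception hierarchy shared across the pipeline."""


class EstrofingerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EstrofingerError, ValueError):
    """A configuration value violates an invariant; names the offending field."""


class ValidationError(EstrofingerError, ValueError):
    """Input data violate a structural invariant (duplicate ids, missing metadata...)."""


class ParseError(EstrofingerError, ValueError):
    """A file could not be parsed; carries row/column context where available."""
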