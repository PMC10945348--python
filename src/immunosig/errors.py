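"""Exception hierarchy shared across the pipeline."""


class ImmunosigError(Exception):
    """Base class for all package errors."""


class FormatError(ImmunosigError):
    """A file does not conform to its declared external format."""


class ValidationError(ImmunosigError):
    """Parsed data violates a domain invariant."""


class ConfigError(ImmunosigError):
    """A configuration object is internally inconsistent."""


class DegenerateInputError(ImmunosigError):
    """Input is degenerate for the requested statistic (e.g. constant)."""
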