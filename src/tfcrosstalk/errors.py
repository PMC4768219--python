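"""Exception hierarchy shared across the pipeline stages."""


class CrosstalkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrosstalkError):
    """A configuration value is outside its documented domain."""


class SizingError(CrosstalkError):
    """Requested geometry does not fit (e.g. too many genes for a chromosome)."""


class DegenerateDataError(CrosstalkError):
    """Input data carry no usable signal (e.g. all replicate variances zero)."""


class InsufficientReplicationError(CrosstalkError):
    """Too few samples to form a test statistic."""


class InputError(CrosstalkError):
    """Malformed or inconsistent user-supplied input."""
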