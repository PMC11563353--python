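"""Exception hierarchy: configuration vs data vs numerical failures."""


class OralfluorError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OralfluorError, ValueError):
    """Invalid or inconsistent configuration values."""


class DataError(OralfluorError, RuntimeError):
    """Malformed or unusable input data."""


class UnusableSampleError(DataError):
    """A lesion/healthy pair with no valid pixels left after preprocessing."""
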