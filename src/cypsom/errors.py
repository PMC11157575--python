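"""Exception hierarchy."""


class CypsomError(Exception):
    """Base class for all package errors."""


class DataError(CypsomError):
    """A structure file or annotation is inconsistent (names the offending record)."""


class ConfigError(CypsomError):
    """A configuration value is invalid (bad isoform name, shape mismatch, ...)."""
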