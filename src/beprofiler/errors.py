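"""Exception hierarchy shared across the package."""


class BeprofilerError(Exception):
    """Base class for all package errors."""


class ValidationError(BeprofilerError):
    """Invalid parameter or malformed input value."""


class CapacityError(BeprofilerError):
    """A combinatorial request exceeds what the alphabet/length can supply."""


class ConfigurationError(BeprofilerError):
    """Inconsistent configuration (e.g. UMI distance too small for mismatch tolerance)."""


class DataError(BeprofilerError):
    """Input data cannot be processed (empty read, zero coverage, zero totals)."""
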