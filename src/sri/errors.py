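"""Exception hierarchy shared across the package."""


class SriError(Exception):
    """Base class for all package errors."""


class DegenerateInputError(SriError, ValueError):
    """Input is structurally valid but empty/too short for the operation."""


class UndefinedIndexError(SriError, ValueError):
    """An acoustic index is mathematically undefined for this input."""


class ValidationError(SriError, ValueError):
    """A label, weight or parameter violates its documented contract."""


class ConfigurationError(SriError, ValueError):
    """Inconsistent configuration (grids, filter banks, bands)."""
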