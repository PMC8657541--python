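"""Exception hierarchy.

All metconn errors derive from :class:`MetconnError`, itself a ``ValueError``
so that callers who do not care about the distinction can catch the builtin.
"""


class MetconnError(ValueError):
    """Base class for all metconn errors."""


class AtlasFormatError(MetconnError):
    """Malformed atlas file (bad JSON shape, duplicate or empty names)."""


class SchemaError(MetconnError):
    """Tabular input does not match the expected column schema."""


class ValidationError(MetconnError):
    """Data violates an invariant (non-positive uptake, asymmetry, ...)."""


class ConfigurationError(MetconnError):
    """A parameter or configuration value is out of its admissible range."""
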