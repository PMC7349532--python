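"""Exception hierarchy shared across the package."""


class CardiowalkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CardiowalkError, ValueError):
    """A parameter object violates its documented invariants."""


class ValidationError(CardiowalkError, ValueError):
    """Data violate a structural invariant (ordering, uniqueness, ranges)."""


class SchemaError(CardiowalkError, ValueError):
    """An on-disk file does not conform to the documented format."""


class MissingStreamError(SchemaError):
    """A required data stream (file) is absent from a session directory."""


class InsufficientDataError(CardiowalkError, ValueError):
    """Too few samples/beats to compute the requested quantity."""
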