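"""Exception hierarchy shared across cernakit modules."""


class CernaKitError(Exception):
    """Base class for all cernakit errors."""


class ConfigError(CernaKitError):
    """A configuration value is invalid; the message names the field."""


class ValidationError(CernaKitError):
    """Input data violates a container invariant (duplicates, NaN, negatives...)."""


class SchemaError(CernaKitError):
    """A tabular input is missing mandatory columns."""


class ParameterError(CernaKitError):
    """An operation parameter is outside its legal range."""


class BoundsError(CernaKitError):
    """A sequence coordinate is out of range."""


class AlphabetError(CernaKitError):
    """A sequence contains a non-nucleotide character."""


class UnknownIdError(CernaKitError):
    """An identifier is not present in the referenced table/matrix/network."""


class DegenerateInputError(CernaKitError):
    """Input has no variance (constant vector) where variance is required."""


class UsageError(CernaKitError):
    """An operation was invoked in an unsupported way (wrong arity, format...)."""
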