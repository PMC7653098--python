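"""Exception hierarchy shared across the package."""


class MitopairError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MitopairError):
    """A bundled or user-supplied configuration resource is missing or malformed."""


class InputError(MitopairError, ValueError):
    """A caller passed an argument outside its documented domain."""


class FormatError(MitopairError):
    """An input file does not conform to its declared format."""


class ValidationError(MitopairError, ValueError):
    """Input data violates an internal consistency requirement."""


class DataError(MitopairError):
    """Data disagrees with the bundled reference (e.g. ref-allele mismatch)."""


class NonEstimableError(MitopairError):
    """A statistical quantity cannot be estimated from the given data."""
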