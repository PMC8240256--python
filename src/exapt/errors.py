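"""Exception types shared across the package."""


class ExaptError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ExaptError, ValueError):
    """A text record could not be parsed (names the offending line)."""


class SchemaError(ExaptError, ValueError):
    """A tabular input is missing required columns."""


class BoundsError(ExaptError, ValueError):
    """An interval exceeds the declared chromosome length."""


class ParameterError(ExaptError, ValueError):
    """An argument is outside its documented range."""


class ConfigurationError(ExaptError, ValueError):
    """A configuration is internally inconsistent or infeasible."""


class SamplingError(ExaptError, ValueError):
    """A random draw cannot be satisfied (e.g. too few repeats in a family)."""
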