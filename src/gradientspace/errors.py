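"""Exception hierarchy shared by all pipeline stages."""


class GradientSpaceError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(GradientSpaceError):
    """An input table does not match the expected column/field layout."""


class ParseError(GradientSpaceError):
    """A cell in an input file could not be interpreted as a number."""


class ConfigurationError(GradientSpaceError):
    """An unknown configuration key or an inconsistent configuration."""


class ValidationError(GradientSpaceError):
    """A parameter or argument is outside its legal range."""


class DegenerateInputError(GradientSpaceError):
    """Input data are degenerate for the requested operation
    (zero-variance parcel, empty network, disconnected graph, ...)."""


class DegreesOfFreedomError(GradientSpaceError):
    """Too few retained frames relative to the number of nuisance
    regressors for a stable projection."""
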