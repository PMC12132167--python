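"""Exception hierarchy.

Every user-facing failure mode raises a subclass of :class:`EccnanoError`
so pipeline drivers can distinguish bad input from bugs.
"""


class EccnanoError(Exception):
    """Base class for all package errors."""


class ParameterError(EccnanoError, ValueError):
    """A function argument violates its documented precondition."""


class ParseError(EccnanoError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(EccnanoError, ValueError):
    """An input file is in an unrecognised format."""


class ReferenceError_(EccnanoError, KeyError):
    """An alignment names a target absent from the consensus set."""


class ConfigurationError(EccnanoError, ValueError):
    """A consensus or run configuration is incomplete or inconsistent."""


class NormalizationError(EccnanoError, ValueError):
    """A sample cannot be normalized (e.g. zero mitochondrial reads)."""
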