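"""Exception hierarchy for the ataxic toolkit.

The CLI maps these onto exit codes: usage/config problems -> 1,
data validation failures -> 2, runtime/state failures -> 3.
"""


class AtaxicError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(AtaxicError):
    """Invalid configuration or unusable parameter combination."""


class ParseError(AtaxicError):
    """A file could not be parsed (malformed cell, bad header, ...)."""


class ValidationError(AtaxicError):
    """Parsed data violates a structural invariant (duplicate ids, shape mismatch, ...)."""


class StateError(AtaxicError):
    """An operation was applied to a matrix in the wrong normalization state."""


class EmptyResultError(AtaxicError):
    """A filter or grouping removed everything; downstream work is impossible."""


class ConstantInputError(AtaxicError):
    """A statistic is undefined because an input vector is constant."""
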