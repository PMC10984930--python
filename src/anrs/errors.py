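"""Exception hierarchy shared across the package.

``ParseError`` marks malformed input files, ``ConfigurationError`` marks
invalid user-supplied settings, and ``ContractViolation`` marks a call that
breaks a documented precondition.
"""


class AnrsError(Exception):
    """Base class for all package errors."""


class ParseError(AnrsError):
    """A data file could not be parsed; the message names the offending line."""


class ConfigurationError(AnrsError):
    """An invalid option, attribute name, or parameter value."""


class ContractViolation(AnrsError):
    """A documented precondition of an operation was violated."""
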