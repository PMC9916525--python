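"""Exception hierarchy.

``UserInputError`` subclasses map to CLI exit code 1; anything else that
escapes is an internal error (exit code 2).
"""


class IpscmineError(Exception):
    """Base class for all package errors."""


class UserInputError(IpscmineError):
    """Bad input supplied by the caller (file contents, parameters)."""


class ConfigError(UserInputError):
    """Invalid simulation or pipeline configuration."""


class FormatError(UserInputError):
    """Malformed external file (TSV/GMT/edge table)."""


class InputError(UserInputError):
    """Semantically invalid in-memory input to an operation."""


class ComputationError(IpscmineError):
    """A numeric precondition was violated during computation."""
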