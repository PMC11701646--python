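"""Exception hierarchy shared across the package.

All domain errors derive from :class:`AssocnetError` so callers (and the CLI)
can distinguish validation problems from genuine bugs.
"""


class AssocnetError(Exception):
    """Base class for all errors raised by assocnet."""


class InvalidParameterError(AssocnetError, ValueError):
    """A configuration parameter is outside its allowed range."""


class InvalidInputError(AssocnetError, ValueError):
    """Input data violates a documented precondition or invariant."""


class ParseError(AssocnetError, ValueError):
    """A text input file could not be parsed into a valid object."""
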