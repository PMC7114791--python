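"""Exception types shared across the package."""


class MtableError(Exception):
    """Base class for all package errors."""


class FormatError(MtableError, ValueError):
    """An input file does not conform to its declared dialect.

    Where possible the message names the offending line number.
    """


class ValidationError(MtableError, ValueError):
    """A value violates a domain invariant (range, uniqueness, ...)."""
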