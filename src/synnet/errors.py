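"""Exception hierarchy shared across the package."""


class SynnetError(Exception):
    """Base class for all package errors."""


class ParseError(SynnetError):
    """A corpus file could not be parsed (malformed row, bad column count)."""


class ValidationError(SynnetError):
    """Parsed content violates a structural invariant (bad governor index, ...)."""
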