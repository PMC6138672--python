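"""Exception hierarchy shared by all pipeline stages."""


class TrapClientError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(TrapClientError):
    """A file could not be parsed (malformed header, non-numeric cell, ...)."""


class ValidationError(TrapClientError):
    """An object violates a domain invariant (duplicate ids, bad residue, ...)."""


class StateError(TrapClientError):
    """An operation was applied to data in the wrong state (e.g. wrong scale)."""
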