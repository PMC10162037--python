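"""Exception hierarchy shared across the package."""


class PatriageError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PatriageError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PatriageError):
    """Input violated a documented invariant (duplicate ids, bad enum tokens, ...)."""
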