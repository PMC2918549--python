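"""Exception hierarchy shared by all pipeline modules."""


class RegioprotError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RegioprotError):
    """A file does not conform to its declared dialect (missing column,
    wrong field count, empty file, ...)."""


class ValidationError(RegioprotError):
    """Well-formed input that violates a domain invariant; carries the
    offending location in the message."""
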