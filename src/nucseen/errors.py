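"""Exception types shared across the package."""


class NucseenError(Exception):
    """Base class for all package errors."""


class FormatError(NucseenError):
    """A file could not be parsed or violates its format contract."""


class ValidationError(NucseenError):
    """Parsed data violates a domain invariant."""
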