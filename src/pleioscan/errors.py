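"""Exception hierarchy shared across modules."""


class PleioscanError(Exception):
    """Base class for all package errors."""


class FormatError(PleioscanError):
    """A file could not be parsed into the expected tabular layout."""


class ValidationError(PleioscanError):
    """Parsed data violates an invariant (duplicates, bad ranges, shapes)."""


class NumericalError(PleioscanError):
    """A numerical routine failed (non-PSD matrix, non-finite result)."""
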