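"""Exception types shared across the package."""


class HarensError(Exception):
    """Base class for all package errors."""


class FormatError(HarensError):
    """A file or table does not conform to the expected dialect."""


class ValidationError(HarensError):
    """Data is well-formed but violates a domain invariant."""
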