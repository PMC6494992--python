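"""Exception hierarchy.

All package-raised errors derive from :class:`EcgGanError`; validation and
shape problems are also ``ValueError`` subclasses so generic callers can
catch them idiomatically.
"""


class EcgGanError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(EcgGanError, ValueError):
    """A configuration or input value violates a documented precondition."""


class ShapeError(ValidationError):
    """Array shapes or layer geometries are inconsistent."""


class DegenerateInputError(ValidationError):
    """The input is degenerate for the requested operation (e.g. constant
    sequence passed to min-max normalization)."""


class FormatError(EcgGanError):
    """A file exists but its contents violate the expected format."""
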