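"""Exception hierarchy.

All package-raised errors derive from :class:`PanploidError` so callers can
catch one type at the CLI boundary.
"""


class PanploidError(Exception):
    """Base class for all errors raised by panploid."""


class FormatError(PanploidError):
    """An on-disk file violates its expected format."""


class ParameterError(PanploidError):
    """A function argument is outside its valid domain."""


class InvariantError(PanploidError):
    """An in-memory object violates a structural invariant."""
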