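"""Exception hierarchy.

User-facing errors (bad input data, bad config) derive from
:class:`LekgraphError` and map to CLI exit code 1; anything else is an
internal error (exit code 2).
"""


class LekgraphError(Exception):
    """Base class for user-facing errors."""


class FormatError(LekgraphError):
    """A file's structure (header, columns) is not as expected."""


class ParseError(LekgraphError):
    """A field could not be parsed; message carries the row number."""


class ValidationError(LekgraphError):
    """Parsed data violates an invariant (duplicates, out-of-range values)."""
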