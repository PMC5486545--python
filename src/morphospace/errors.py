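"""Exception hierarchy for morphospace.

All data-level failures derive from :class:`MorphospaceError`, so callers
(and the CLI) can distinguish bad input from programming errors.
"""


class MorphospaceError(Exception):
    """Base class for all morphospace data errors."""


class MissingDataError(MorphospaceError):
    """An operation that requires a complete matrix met missing entries."""

    def __init__(self, cells):
        self.cells = list(cells)
        shown = ", ".join(f"({c}, {f})" for c, f in self.cells[:10])
        more = "" if len(self.cells) <= 10 else f" and {len(self.cells) - 10} more"
        super().__init__(f"matrix has missing entries at {shown}{more}")


class FieldError(MorphospaceError):
    """Operation invoked with an incompatible field tag."""


class DegenerateMatrixError(MorphospaceError):
    """Normalization constant vanished (e.g. Z = 0 in the co-occurrence matrix)."""


class FormatError(MorphospaceError):
    """A file could not be parsed under the declared dialect."""
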