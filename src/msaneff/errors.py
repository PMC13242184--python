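"""Exception hierarchy.

All package-raised errors derive from :class:`MsaError` so callers can catch
one base class; I/O problems propagate as the builtin ``OSError`` family and
are deliberately *not* wrapped, keeping "file unreadable" distinct from
"file invalid".
"""


class MsaError(Exception):
    """Base class for alignment-related errors."""


class MsaParseError(MsaError):
    """Structurally invalid input for the declared format."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnrecognizedFormatError(MsaError):
    """Format auto-detection found no structural cue."""


class EncodingError(MsaError):
    """A character outside the alphabet's permitted sets."""


class MergeError(MsaError):
    """Incompatible alignments passed to merge."""


class OptionError(MsaError):
    """Invalid NEFF option value."""


class EmptyAlignmentError(MsaError):
    """No rows, or preprocessing removed every column."""


class MultimerSpecError(MsaError):
    """Chain segmentation inconsistent with the alignment."""
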