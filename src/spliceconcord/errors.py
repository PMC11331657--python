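"""Exception hierarchy for the splice-concordance pipeline."""


class SpliceConcordError(Exception):
    """Base class for all package errors."""


class FormatError(SpliceConcordError):
    """A table or sequence file is structurally invalid (e.g. missing column)."""


class RowError(SpliceConcordError):
    """A single data row could not be parsed or violates a field constraint."""

    def __init__(self, message: str, row_index: int | None = None):
        if row_index is not None:
            message = f"row {row_index}: {message}"
        super().__init__(message)
        self.row_index = row_index


class MissingCoordinateError(SpliceConcordError):
    """An event lacks a coordinate component required for its type."""


class DuplicateKeyError(SpliceConcordError):
    """Two events within one contrast share a matching key."""


class WindowBoundsError(SpliceConcordError):
    """A junction window extends beyond the contig."""


class NoWindowsError(SpliceConcordError):
    """No junction windows survived filtering for a requested group."""


class ConfigError(SpliceConcordError):
    """Invalid pipeline or generator configuration."""
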