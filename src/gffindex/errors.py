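"""Exception hierarchy.

Usage errors (bad arguments) are distinguished from data/format errors so the
command-line layer can map them to distinct exit codes.
"""


class GffIndexError(Exception):
    """Base class for all errors raised by this package."""


class DataError(GffIndexError):
    """A problem with input data or on-disk indices (exit code 2 in the CLI)."""


class MalformedLineError(DataError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


class MalformedBedError(DataError):
    def __init__(self, message: str, line_no: int):
        super().__init__(f"BED line {line_no}: {message}")
        self.line_no = line_no


class DanglingParentError(DataError):
    def __init__(self, parent_id: str, line_no: int):
        super().__init__(
            f"line {line_no}: Parent={parent_id!r} references an ID never "
            f"defined in the file"
        )
        self.parent_id = parent_id
        self.line_no = line_no


class HierarchyCycleError(DataError):
    def __init__(self, feature_no: int):
        super().__init__(f"parent chain of feature #{feature_no} forms a cycle")
        self.feature_no = feature_no


class InvalidIntervalError(DataError):
    pass


class InvalidQueryError(GffIndexError):
    pass


class CapacityError(DataError):
    """A table exceeds the fixed integer width of the binary index format."""


class StaleIndexError(DataError):
    """The source file changed since the index was written."""


class MissingIndexError(DataError):
    def __init__(self, extension: str, path):
        super().__init__(f"missing index file {path} ({extension})")
        self.extension = extension
        self.path = path


class NotIndexedError(DataError):
    """An attribute key was not among the keys indexed at build time."""


class UnknownIdError(DataError):
    """A requested feature identifier is absent from the index."""


class FormatError(DataError):
    """Malformed SAM/BAM or index payload."""
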