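"""Exception hierarchy shared across the package.

Every contract violation raises a distinct, named error so callers (and the
CLI, which maps data errors to exit code 3) can react specifically.
"""


class SamgsrError(Exception):
    """Base class for all package errors."""


class DataError(SamgsrError):
    """Malformed or inconsistent input data."""


class MalformedHeaderError(DataError):
    """Expression TSV header is missing or not parseable."""


class NonNumericValueError(DataError):
    """A matrix cell could not be parsed as a number."""


class UnknownSampleError(DataError):
    """A labels file names a sample absent from the expression matrix."""


class MissingLabelError(DataError):
    """A sample in the expression matrix has no label."""


class GmtFormatError(DataError):
    """A GMT line has fewer than three fields."""


class DuplicateSetNameError(DataError):
    """Two GMT lines declare the same gene-set name."""


class EmptyMappingError(DataError):
    """No gene set survives mapping onto a study's gene universe.

    Usually indicates a gene-ID namespace mismatch (e.g. symbols vs Ensembl).
    """


class ZeroLibraryError(DataError):
    """A count-matrix column sums to zero, so CPM is undefined."""


class ClassSizeError(DataError):
    """A phenotype class has fewer samples than the operation requires."""


class SchemeMismatchError(DataError):
    """A permutation scheme was built for a different sample set."""


class EnumerationTooLargeError(SamgsrError):
    """Exact permutation enumeration exceeds the configured cap."""


class EmptySelectionError(SamgsrError):
    """The final gene selection is empty; the tuning grid is attached."""

    def __init__(self, message: str, grid=None):
        super().__init__(message)
        self.grid = grid
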