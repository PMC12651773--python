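"""Exception hierarchy for digestnn.

Every error raised on a user-facing code path derives from :class:`DigestnnError`
so callers can catch the package's failures with a single except clause.
"""


class DigestnnError(Exception):
    """Base class for all digestnn errors."""


class SchemaError(DigestnnError):
    """A required column is missing or mis-typed in an input table."""


class ParseError(DigestnnError):
    """A cell could not be parsed as a number; message carries the row index."""


class DomainError(DigestnnError):
    """A scalar argument lies outside its physically meaningful domain."""


class DegenerateFeatureError(DigestnnError):
    """A feature column has zero variance and cannot be standardized."""


class ShapeError(DigestnnError):
    """Matrix dimensions do not match the expected layout."""


class ConfigError(DigestnnError):
    """A configuration object violates its invariants."""


class InsufficientDataError(DigestnnError):
    """Too few rows to run the requested operation."""


class DataError(DigestnnError):
    """A dataset is empty or otherwise unusable for training/evaluation."""


class FoldError(DigestnnError):
    """Cross-validation fold count is incompatible with the dataset size."""
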