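"""Exception hierarchy shared across the package."""


class Th2ScoreError(Exception):
    """Base class for all package errors."""


class SchemaError(Th2ScoreError):
    """A required column is missing or the column mapping is invalid."""


class RowParseError(Th2ScoreError):
    """A row-level value could not be parsed; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EmptyInputError(Th2ScoreError):
    """An operation received an empty cohort or empty value collection."""


class MissingDataError(Th2ScoreError):
    """A participant lacks a biomarker required by the operation."""


class DegenerateTableError(Th2ScoreError):
    """A contingency table has a zero row or column margin."""
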