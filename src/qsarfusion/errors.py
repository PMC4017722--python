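"""Exception hierarchy shared across the package."""


class QsarFusionError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(QsarFusionError):
    """A required column is missing from an input table."""


class ParseError(QsarFusionError):
    """A cell failed to parse (non-numeric or non-positive activity).

    Carries the zero-based data-row index in ``row``.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class IntegrityError(QsarFusionError):
    """A table-level invariant is violated (e.g. duplicate compound ids)."""


class CoverageError(QsarFusionError):
    """A score table does not cover every compound id it is evaluated against.

    ``missing`` lists the offending ids.
    """

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class DegenerateInputError(QsarFusionError):
    """An input is numerically degenerate (zero variance, too few points)."""
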