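"""Exception hierarchy shared across the package."""


class StraitpopError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StraitpopError):
    """A required column is missing or the file header is malformed."""


class ValidationError(StraitpopError):
    """One or more rows violate a data-model invariant.

    Carries the per-row messages so callers can report line numbers.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        msg = "; ".join(str(e) for e in self.row_errors[:5])
        if len(self.row_errors) > 5:
            msg += f" (+{len(self.row_errors) - 5} more)"
        super().__init__(f"{len(self.row_errors)} invalid row(s): {msg}")


class ConsistencyError(StraitpopError):
    """Tag histories are internally inconsistent (e.g. recapture of an
    unmarked tag)."""


class UndefinedEstimateError(StraitpopError):
    """The estimator is undefined for the given occasion series (no marked
    animals ever at risk)."""


class EmptyGridError(StraitpopError):
    """A raster operation received a grid with no usable cells."""
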