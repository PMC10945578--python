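"""Exception types shared across the package."""


class GDCATError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GDCATError):
    """A file violated the expected tab-separated / GMT layout."""


class GeneLookupError(GDCATError, KeyError):
    """A requested gene or gene-tissue combination does not exist.

    Carries ``suggestions``: near-miss symbols to help diagnose typos.
    """

    def __init__(self, message: str, suggestions: list[str] | None = None):
        super().__init__(message)
        self.suggestions = suggestions or []

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        msg = self.args[0]
        if self.suggestions:
            msg += " (did you mean: " + ", ".join(self.suggestions) + "?)"
        return msg


class InsufficientDataError(GDCATError):
    """Fewer complete observations than the statistic requires."""


class UndefinedCorrelationError(GDCATError):
    """A correlation is undefined (zero dispersion in an input vector)."""


class SignatureError(GDCATError):
    """A cell-type signature matrix is unusable (rank deficient, too few
    shared genes, negative entries...)."""
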