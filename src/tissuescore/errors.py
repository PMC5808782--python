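"""Exception hierarchy shared across the package."""


class TissueScoreError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(TissueScoreError):
    """A file could not be parsed; message names the offending line."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class ValidationError(TissueScoreError):
    """Input data violates a documented contract."""


class FitError(TissueScoreError):
    """Curve fitting failed; carries the best candidate found so far."""

    def __init__(self, message: str, best=None, rss: float | None = None):
        self.best = best
        self.rss = rss
        super().__init__(message)


class UndefinedCorrelationError(TissueScoreError):
    """Pearson correlation is undefined (too few points or zero variance)."""
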