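"""Exception hierarchy shared across the package."""


class BiocnetError(Exception):
    """Base class for all package errors."""


class FormatError(BiocnetError):
    """A file or table does not have the expected layout (missing columns,
    unknown class token, unparseable content)."""


class ValidationError(BiocnetError):
    """Structurally well-formed input violates a domain invariant
    (duplicate code, unknown code, biophysical-to-biophysical dependency...).

    ``violations`` carries every detected violation when the caller asked
    for an exhaustive check; the message always names the first one.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = violations if violations is not None else [message]


class AnalysisError(BiocnetError):
    """An operation was asked of a network that cannot support it
    (no edges, too few nodes, missing ego node...)."""
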