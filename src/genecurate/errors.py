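"""Exception hierarchy shared across the package."""


class GeneCurateError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GeneCurateError):
    """Malformed annotation or intermediate-table input.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ConfigurationError(GeneCurateError):
    """Inconsistent or incomplete run configuration."""


class AlphabetError(GeneCurateError):
    """Sequence contains characters outside the supported nucleotide alphabet."""


class GenomeLookupError(GeneCurateError, LookupError):
    """A scaffold named by a gene model is absent from the genome."""


class BoundsError(GeneCurateError):
    """A coordinate falls outside its scaffold."""


class GenerationError(GeneCurateError):
    """The synthetic-fixture generator cannot satisfy the requested parameters."""
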