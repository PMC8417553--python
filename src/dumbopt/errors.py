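"""Exception hierarchy shared across the toolkit."""


class DumboptError(Exception):
    """Base class for all toolkit errors."""


class CodonTableSchemaError(DumboptError, ValueError):
    """Codon-usage table violates the CSV schema (missing/duplicate codon, bad column)."""


class GeneticCodeMismatchError(DumboptError, ValueError):
    """A codon/amino-acid pair contradicts the standard genetic code."""


class SequenceFrameError(DumboptError, ValueError):
    """Coding sequence length is not a multiple of three."""


class SequenceAlphabetError(DumboptError, ValueError):
    """Sequence contains characters outside the unambiguous DNA alphabet."""


class PrematureStopError(DumboptError, ValueError):
    """Internal (non-terminal) stop codon found in a coding sequence."""

    def __init__(self, position: int, codon: str):
        self.position = position
        self.codon = codon
        super().__init__(
            f"internal stop codon {codon!r} at codon position {position}"
        )


class InsufficientLengthError(DumboptError, ValueError):
    """Sequence shorter than one sliding window."""


class ZeroIntensityError(DumboptError, ZeroDivisionError):
    """Polarization undefined: total emission intensity is zero."""


class FitFailureError(DumboptError, RuntimeError):
    """Nonlinear fit failed to converge or parameters are unidentifiable."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class DataInsufficiencyError(DumboptError, ValueError):
    """Too few data points or replicates to support the requested analysis."""


class ConfigurationError(DumboptError, ValueError):
    """Invalid or missing configuration value (e.g. absent seed for random mode)."""
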