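"""Exception hierarchy shared across the package."""


class LysocleaveError(Exception):
    """Base class for all package errors."""


class InvalidAlphabetError(LysocleaveError):
    """A character fell outside the expected alphabet.

    Carries the 0-based ``position`` and the offending ``character`` when
    known.
    """

    def __init__(self, message, position=None, character=None):
        super().__init__(message)
        self.position = position
        self.character = character


class AnnotationMismatchError(LysocleaveError):
    """Annotation track length does not match the sequence."""


class MissingAnnotationError(LysocleaveError):
    """A model needs ss/rsa tracks the input sequence does not carry."""


class PatternSyntaxError(LysocleaveError):
    """A consensus pattern string could not be parsed."""

    def __init__(self, message, token=None):
        super().__init__(message)
        self.token = token


class InsufficientDataError(LysocleaveError):
    """Too little data to build a frequency table or matrix."""


class WindowLengthError(LysocleaveError):
    """A training window is not exactly 8 characters long."""


class DegenerateTrainingError(LysocleaveError):
    """Weight fitting received a single-class corpus."""


class CalibrationError(LysocleaveError):
    """Threshold calibration received a single-class score list."""


class SplitError(LysocleaveError):
    """Substrate-level split cannot be performed."""


class EvaluationError(LysocleaveError):
    """Evaluation received an empty test set."""


class MassUndefinedError(LysocleaveError):
    """Molecular properties undefined for a non-canonical peptide."""


class GenerationError(LysocleaveError):
    """Synthetic corpus generation could not satisfy its constraints."""


class ConfigError(LysocleaveError):
    """Invalid run configuration."""


class ParseError(LysocleaveError):
    """Malformed input file."""

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line
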