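"""Exception hierarchy for the speechnet pipeline."""


class SpeechNetError(Exception):
    """Base class for all speechnet errors."""


class ConlluParseError(SpeechNetError):
    """Malformed CoNLL-U input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TranscriptValidationError(SpeechNetError):
    """A parsed transcript violates a structural invariant (heads, roots, cycles)."""


class EmptyInputError(SpeechNetError):
    """An operation received an input with no usable content."""


class InsufficientInputError(SpeechNetError):
    """An operation received fewer observations than it requires."""


class ConvergenceError(SpeechNetError):
    """An iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, n_iter: int | None = None, gap: float | None = None):
        self.n_iter = n_iter
        self.gap = gap
        super().__init__(message)
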