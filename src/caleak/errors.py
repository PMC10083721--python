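"""Exception hierarchy shared across the package."""


class CaleakError(Exception):
    """Base class for all package-specific errors."""


class CalibrationRangeError(CaleakError):
    """A ratio sample lies outside the calibratable range [R_min, R_max)."""

    def __init__(self, message: str, indices=None):
        super().__init__(message)
        self.indices = tuple(indices) if indices is not None else ()


class DomainError(CaleakError):
    """An argument violates a physical-domain precondition (sign, range)."""


class DegenerateRatesError(CaleakError):
    """Operation undefined at k_leak == k_clear (gain has a pole there)."""


class MissingEventError(CaleakError):
    """A protocol event label is absent from the trace metadata."""


class FitFailureError(CaleakError):
    """A parameter estimate could not be obtained; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StageError(CaleakError):
    """Pipeline-stage failure; names the stage for exit-code mapping."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
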