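"""Exception hierarchy shared across the package."""


class PlasmaProbError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PlasmaProbError):
    """Invalid cohort or run configuration."""


class FitError(PlasmaProbError):
    """Density fitting failed (degenerate input or non-convergence)."""


class TrainingError(PlasmaProbError):
    """Classifier training failed (class too small, fold too small, ...)."""


class ClassificationError(PlasmaProbError):
    """A record could not be classified (missing biomarker, undefined probability)."""


class EvaluationError(PlasmaProbError):
    """Performance evaluation failed (single-class input, length mismatch, ...)."""


class MissingColumnError(PlasmaProbError):
    """A required CSV column is absent."""

    def __init__(self, column: str, context: str = ""):
        self.column = column
        msg = f"required column {column!r} is missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)
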