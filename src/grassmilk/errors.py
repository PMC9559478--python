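"""Exception hierarchy for the grassmilk pipeline."""


class GrassmilkError(Exception):
    """Base class for all package errors."""


class InputError(GrassmilkError, ValueError):
    """Invalid argument value (out-of-range month, bad fraction, empty input...)."""


class ConfigurationError(GrassmilkError, ValueError):
    """Invalid or incomplete configuration (empty schema, unmapped cluster...)."""


class SchemaError(GrassmilkError, ValueError):
    """A table does not carry the required columns."""

    def __init__(self, missing: list[str] | None = None, message: str | None = None):
        self.missing = list(missing or [])
        if message is None:
            message = "missing required column(s): " + ", ".join(self.missing)
        super().__init__(message)


class DegenerateLabelError(GrassmilkError, ValueError):
    """After filtering, one of the two modelling classes is empty."""


class UndefinedMetricError(GrassmilkError, ValueError):
    """A metric is undefined for the given input (e.g. single-class AUC)."""


class EmptySubsetError(GrassmilkError, ValueError):
    """A variable-selection step removed every predictor."""
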