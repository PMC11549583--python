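"""Exception hierarchy for the pnavax pipeline."""


class PnavaxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PnavaxError):
    """An input table does not have the documented layout (e.g. a missing column)."""


class IntegrityError(PnavaxError):
    """Tables parse but are mutually inconsistent (dangling tie, duplicate ego id)."""


class DegenerateInputError(PnavaxError):
    """A quantity is requested on an input where it is mathematically undefined."""


class ConfigError(PnavaxError):
    """A configuration value is outside its admissible range."""


class SeparationError(PnavaxError):
    """Complete separation detected for a predictor in a logistic fit."""

    def __init__(self, predictor: str):
        self.predictor = predictor
        super().__init__(
            f"complete separation: outcome is constant within a level of {predictor!r}"
        )


class EmptyFrameError(PnavaxError):
    """Filtering removed every analysis row."""
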