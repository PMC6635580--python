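"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when data handed to an operation violates its contract."""


class InvalidConfigError(ValueError):
    """Raised when a configuration value is outside its admissible range."""


class UndefinedIndexError(InvalidInputError):
    """Raised when a sequence index is mathematically undefined (0/0)."""


class FitFailureError(RuntimeError):
    """Raised when every optimizer restart fails; carries diagnostics."""

    def __init__(self, message, restarts=None):
        super().__init__(message)
        self.restarts = restarts or []
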