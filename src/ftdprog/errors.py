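"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid generator or run configuration."""


class SchemaError(ValueError):
    """Input table does not match the expected cohort schema."""

    def __init__(self, message: str, missing_columns: list[str] | None = None):
        super().__init__(message)
        self.missing_columns = missing_columns or []


class InsufficientDataError(ValueError):
    """Too few complete records for the requested fit."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear terms."""

    def __init__(self, terms: list[str]):
        super().__init__(f"rank-deficient design; collinear term(s): {', '.join(terms)}")
        self.terms = terms


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge; carries the last parameter state."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params
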