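"""Exception hierarchy shared across the package."""


class SubtypeBenchError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SubtypeBenchError):
    """A file could not be parsed into the expected structure."""


class DuplicateIDError(ParseError):
    """Duplicate gene or sample identifiers where uniqueness is required."""


class FormatError(ParseError):
    """Malformed line or missing fields in an input file."""


class ConfigError(SubtypeBenchError):
    """Invalid or inconsistent run configuration."""


class ContractError(SubtypeBenchError):
    """An operation was called with inputs violating its contract."""


class ConvergenceError(SubtypeBenchError):
    """An iterative procedure failed to converge within its budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateInputError(SubtypeBenchError):
    """Input admits no meaningful answer (e.g. all degrees equal)."""


class SeedGeneError(SubtypeBenchError):
    """No usable seed genes after restriction to the network."""


class StabilityError(SubtypeBenchError):
    """Too many resamples failed during stability estimation."""
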