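"""Exception types shared across the package."""


class MthetError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MthetError, ValueError):
    """A model or run parameter lies outside its valid range."""


class ExtinctCellError(MthetError, ValueError):
    """A cell with zero mtDNA molecules cannot be simulated."""


class EmptyInputError(MthetError, ValueError):
    """An operation received an empty collection or file."""


class InsufficientDataError(MthetError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(MthetError, ValueError):
    """Input is degenerate (e.g. mean heteroplasmy 0 or 1, zero variance)."""


class BoundaryError(MthetError, ValueError):
    """Heteroplasmy at 0 or 1 where the open interval is required."""


class RankDeficiencyError(MthetError, ValueError):
    """Regression design matrix has no variation in the predictor."""


class ConvergenceError(MthetError, RuntimeError):
    """An iterative numerical procedure failed to reach tolerance."""


class SchemaError(MthetError, ValueError):
    """An input table is missing a required column or is malformed."""
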