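"""Exception hierarchy shared across the analysis stages."""


class LipokineError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LipokineError):
    """Invalid generator or pipeline configuration."""


class DesignError(LipokineError):
    """The factorial design is unbalanced, has empty cells, or mismatched sizes."""


class DegenerateVarianceError(LipokineError):
    """Zero residual variance; F statistics are undefined."""


class DegenerateVariableError(LipokineError):
    """A variable is constant and cannot be standardized."""


class DegenerateLabelError(LipokineError):
    """A classification task received fewer than two classes."""


class UndefinedRatioError(LipokineError):
    """Ratio denominator is non-positive."""


class DomainError(LipokineError):
    """An argument lies outside the mathematically valid domain."""


class RankError(LipokineError):
    """Requested more components than the data matrix can support."""


class CollinearityError(LipokineError):
    """Rank-deficient design matrix in a linear model."""


class CohortFormatError(LipokineError):
    """A cohort table file could not be parsed or lacks required columns."""
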