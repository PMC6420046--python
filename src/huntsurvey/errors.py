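"""Exception hierarchy shared across the package.

Distinct classes exist so the CLI can map error families to distinct exit
codes (config vs data-format vs estimation).
"""


class HuntSurveyError(Exception):
    """Base class for all package errors."""


class DomainError(HuntSurveyError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class SizeError(HuntSurveyError, ValueError):
    """A requested sample size is infeasible for the available pool."""


class ConsistencyError(HuntSurveyError, ValueError):
    """Survey data violate the nested multiphase structure."""


class EstimationError(HuntSurveyError, ValueError):
    """An estimator cannot be evaluated on the supplied data."""


class ConfigError(HuntSurveyError, ValueError):
    """A scenario or CLI configuration is invalid."""


class DataFormatError(HuntSurveyError, ValueError):
    """A survey input file cannot be parsed into the expected tables."""


class DegenerateSizeWarning(UserWarning):
    """A variance estimate is undefined because a dispersion term has
    fewer than two contributing units; NaN is returned instead of a value."""
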