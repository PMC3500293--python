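"""Exception hierarchy shared across the pipeline stages."""


class BatsigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BatsigError):
    """A config, metadata table or input combination is invalid."""


class DomainError(BatsigError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class InsufficientDataError(BatsigError):
    """Too few replicates / complete pairs to run a statistic."""


class EmptySetError(BatsigError):
    """A gene set is empty after removing unusable members."""


class MismatchedPanelsError(ConfigurationError):
    """Two set correlations were computed on different sample panels."""
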