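"""Exception hierarchy for picselect."""


class PicselectError(Exception):
    """Base class for all picselect errors."""


class DomainError(PicselectError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateDataError(PicselectError, ValueError):
    """The data admit no proper scale estimate (e.g. all observations identical)."""


class DesignMatrixError(PicselectError, ValueError):
    """The design matrix is rank deficient or otherwise unusable."""


class InsufficientDataError(PicselectError, ValueError):
    """Too few observations for the requested fit or criterion."""


class ConvergenceError(PicselectError, RuntimeError):
    """The optimizer failed to converge after all restarts.

    Carries the best iterate found in ``best_result`` when available.
    """

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class DataLoadError(PicselectError, ValueError):
    """A tabular input file could not be parsed into a clean numeric table."""


class ConfigError(PicselectError, ValueError):
    """An invalid simulation or CLI configuration."""
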