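"""Exception types shared across the package."""


class CaftError(Exception):
    """Base class for all package-specific errors."""


class EmptyTableError(CaftError):
    """A filter removed every sample (or the input table was empty)."""


class NotEstimableError(CaftError):
    """A taxon carries no rank information (e.g. every observation censored)."""


class DesignError(CaftError):
    """The covariate design is unusable (rank deficient, uncentered, ...)."""
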