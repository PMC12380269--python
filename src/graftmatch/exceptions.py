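"""Exception hierarchy for graftmatch."""


class GraftmatchError(Exception):
    """Base class for all graftmatch errors."""


class ConfigurationError(GraftmatchError):
    """An invalid configuration value; the message names the offending field."""


class EncodingError(GraftmatchError):
    """Covariate encoding failed (e.g. zero-variance continuous covariate)."""


class MatchingError(GraftmatchError):
    """A matching operation received an invalid input (e.g. empty treated set)."""


class FittingError(GraftmatchError):
    """A model fit failed (e.g. perfect separation in the propensity model)."""


class AnalysisError(GraftmatchError):
    """A balance or outcome analysis received degenerate input."""
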