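"""Exception hierarchy for confmvpa.

All errors derive from :class:`ConfmvpaError` (a ``ValueError``) so callers
can catch package errors with a single except clause while standard
``ValueError`` handling still works.
"""


class ConfmvpaError(ValueError):
    """Base class for all confmvpa errors."""


class ConfigurationError(ConfmvpaError):
    """Invalid simulation or analysis configuration."""


class AlignmentError(ConfmvpaError):
    """Structural mismatch between a pattern matrix and its trial table."""


class DataError(ConfmvpaError):
    """Data cannot support the requested operation (empty class, bad split)."""


class EstimationError(ConfmvpaError):
    """Single-trial GLM estimation failed (e.g. rank-deficient design)."""


class TuningError(ConfmvpaError):
    """Regularization tuning failed (all cross-validation folds degenerate)."""
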