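"""Exception hierarchy for the neurofatigue pipeline.

Every stage raises a subclass of :class:`NeurofatigueError`, so callers
(including the CLI) can map failures to machine-readable categories.
"""


class NeurofatigueError(Exception):
    """Base class for all pipeline errors."""

    category = "error"


class InvalidConfigError(NeurofatigueError):
    """A configuration value violates its documented constraints."""

    category = "invalid-config"


class InvalidInputError(NeurofatigueError):
    """A scalar input to a metric computation is out of its valid domain."""

    category = "invalid-input"


class InvalidResponseError(NeurofatigueError):
    """An evoked-response trace cannot yield valid metrics (e.g. no positive peak)."""

    category = "invalid-response"


class OnsetNotFoundError(NeurofatigueError):
    """No sustained threshold crossing found in the trace."""

    category = "onset-not-found"


class TargetNotReachedError(NeurofatigueError):
    """The velocity trace never reaches the target angular velocity."""

    category = "target-not-reached"


class InsufficientSamplesError(NeurofatigueError):
    """An analysis window contains too few samples."""

    category = "insufficient-samples"


class NyquistViolationError(NeurofatigueError):
    """Sampling rate too low for the requested frequency content."""

    category = "nyquist-violation"


class UnbalancedDesignError(NeurofatigueError):
    """Repeated-measures table has missing cells."""

    category = "unbalanced-design"


class CollinearityError(NeurofatigueError):
    """Design matrix is rank deficient or contains a constant column."""

    category = "collinearity"


class FitFailureError(NeurofatigueError):
    """Nonlinear fit failed to converge; message carries diagnostics."""

    category = "fit-failure"
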