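"""Exception hierarchy for the pesmorph pipeline."""


class PesmorphError(Exception):
    """Base class for all pesmorph errors."""


class ValidationError(PesmorphError, ValueError):
    """Invalid input data or configuration (CLI exit code 1)."""


class ComputationError(PesmorphError, RuntimeError):
    """A numerically infeasible model fit, e.g. a singular covariance (CLI exit code 2)."""
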