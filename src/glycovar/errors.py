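"""Exception types shared across the pipeline."""


class GlycovarError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GlycovarError):
    """Invalid configuration; the message names the offending field."""


class EligibilityError(GlycovarError):
    """A subject-level derivation could not be performed (e.g. no index)."""


class MeasureError(GlycovarError):
    """A derived measure is undefined for the given input."""


class BalanceError(GlycovarError):
    """Entropy balancing failed (infeasible constraints or non-convergence)."""


class ModelError(GlycovarError):
    """An outcome model could not be fit."""
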