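"""Exception hierarchy.

Exit-code mapping used by the CLI: config errors -> 2, validation errors -> 3,
estimation/positivity errors -> 4.
"""


class SepEffectsError(Exception):
    """Base class for all package errors."""


class ConfigError(SepEffectsError):
    """Invalid configuration, design, model or partition."""


class InputError(SepEffectsError):
    """Malformed input file (schema mismatch, bad column, bad value)."""


class ValidationError(SepEffectsError):
    """A cohort violates a structural invariant (named subject/interval/rule)."""


class EstimationError(SepEffectsError):
    """An estimator cannot be computed (e.g. empty treatment arm)."""


class PositivityError(EstimationError):
    """A conditional probability is undefined (empty stratum) or a weight
    denominator is zero; carries the offending stratum description."""

    def __init__(self, message, *, target=None, interval=None, stratum=None, subject=None):
        super().__init__(message)
        self.target = target
        self.interval = interval
        self.stratum = stratum
        self.subject = subject
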