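"""Exception taxonomy shared across the package.

Validation errors indicate bad inputs (CLI exit code 2); estimation errors
indicate that a statistically well-posed request could not be answered from
the data at hand (CLI exit code 1).
"""


class RDThreshError(Exception):
    """Base class for all package errors."""


class ValidationError(RDThreshError, ValueError):
    """Malformed input: bad file, bad configuration, violated invariant."""


class EstimationError(RDThreshError, RuntimeError):
    """Estimation failed: degenerate design, too few observations, etc."""


class WeakIdentificationError(EstimationError):
    """Fuzzy-design compliance discontinuity too small to identify effects."""


class InferenceError(RDThreshError, RuntimeError):
    """Resampling inference failed (e.g. most bootstrap replicates errored)."""


class ExtrapolationWarning(UserWarning):
    """Effect curve evaluated outside its stated validity interval."""
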