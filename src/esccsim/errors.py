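"""Exception types raised by the model.

All inherit from builtin exception categories so callers can catch broadly
(``ValueError``) or narrowly (e.g. ``ConservationError``).
"""


class DomainError(ValueError):
    """An argument lies outside the domain the operation is defined on."""


class ValidationError(ValueError):
    """A parameter set or derived quantity violates a structural invariant."""


class ConservationError(RuntimeError):
    """Cohort occupancy failed to sum to its initial mass within tolerance."""


class UndefinedResultError(ZeroDivisionError):
    """A ratio-type output has an empty denominator (no survivors, no events)."""
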