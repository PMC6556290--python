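"""Transition hazards: age-dependent onset and duration-dependent progression.

Onset of the first precancerous lesion (normal mucosa -> BCH/mD) follows a
piecewise log-linear hazard in transformed age u = age - A1 with knots at the
ages A1 < A2 < A3 (defaults 15, 40, 100):

    log lambda1(u) = beta0 + slope_k * u + correction_k        (segment k)

Four betas are printed for this hazard but only two age segments are active
inside the simulated age span, and the printed correction sum is ambiguous
about which knot terms enter which segment. Several defensible readings are
therefore implemented and selectable via ``OnsetHazardParams.form``:

``piecewise_offset`` (default)
    Slope beta1 below the A2 knot, slope beta2 above it, and the upper
    segment carries *both* printed knot terms U2*(beta1-beta2) +
    U3*(beta2-beta3) (U_k = A_k - A1). This uses all four betas and is the
    reading that reproduces the published verification analyses; note the
    log-hazard steps down at A2 (it is not continuous there).
``piecewise_continuous``
    Classic continuous linear spline: slope beta1 / beta2 / beta3 per
    segment, each knot adding the continuity correction U_k*(beta_{k-1} -
    beta_k). Continuous everywhere.
``piecewise_continuous_beta3``
    As above but with beta3 as the middle-segment slope (beta2 unused).
``chronological``
    Continuous spline on raw age instead of u (corrections A_k*(beta_{k-1} -
    beta_k)).

Progression out of BCH/mD decelerates with time already spent in the state:
log lambda2 = alpha0 - alpha1 * T_d with T_d the duration in years.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError

ONSET_FORMS = (
    "piecewise_offset",
    "piecewise_continuous",
    "piecewise_continuous_beta3",
    "chronological",
)


@dataclass(frozen=True)
class OnsetHazardParams:
    """Parameters of the normal -> BCH/mD onset hazard."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    a1: float = 15.0
    a2: float = 40.0
    a3: float = 100.0
    form: str = "piecewise_offset"

    def __post_init__(self) -> None:
        vals = (self.beta0, self.beta1, self.beta2, self.beta3,
                self.a1, self.a2, self.a3)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("onset parameters must be finite")
        if not self.a1 < self.a2 < self.a3:
            raise ValidationError("knot ages must satisfy A1 < A2 < A3")
        if self.form not in ONSET_FORMS:
            raise ValidationError(f"unknown onset form {self.form!r}")


@dataclass(frozen=True)
class ProgressionHazardParams:
    """Parameters of the duration-dependent BCH/mD -> MD hazard."""

    alpha0: float
    alpha1: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha0) and np.isfinite(self.alpha1)):
            raise ValidationError("progression parameters must be finite")


def onset_hazard(age, params: OnsetHazardParams):
    """Annual onset rate lambda1 at ``age`` (scalar or array) in years."""
    age = np.asarray(age, dtype=float)
    if np.any(age < params.a1) or np.any(age > 100.0):
        raise DomainError(f"age outside [{params.a1}, 100]")
    b0, b1, b2, b3 = params.beta0, params.beta1, params.beta2, params.beta3

    if params.form == "chronological":
        t, k2, k3 = age, params.a2, params.a3
    else:
        t = age - params.a1
        k2, k3 = params.a2 - params.a1, params.a3 - params.a1

    c2 = k2 * (b1 - b2)           # knot-2 term
    c3 = k3 * (b2 - b3)           # knot-3 term
    if params.form == "piecewise_offset":
        log_lam = np.where(t < k2, b0 + t * b1, b0 + t * b2 + c2 + c3)
    elif params.form == "piecewise_continuous_beta3":
        c2b = k2 * (b1 - b3)
        log_lam = np.where(t < k2, b0 + t * b1, b0 + t * b3 + c2b)
    else:  # continuous spline, u-scale or chronological
        log_lam = np.where(
            t < k2,
            b0 + t * b1,
            np.where(t < k3, b0 + t * b2 + c2, b0 + t * b3 + c2 + c3),
        )
    lam = np.exp(log_lam)
    return float(lam) if lam.ndim == 0 else lam


def bchmd_progression_hazard(duration, params: ProgressionHazardParams):
    """Annual BCH/mD -> MD rate lambda2 after ``duration`` years in state."""
    duration = np.asarray(duration, dtype=float)
    if np.any(duration < 0):
        raise DomainError("duration must be non-negative")
    lam = np.exp(params.alpha0 - params.alpha1 * duration)
    return float(lam) if lam.ndim == 0 else lam


def rate_to_prob(rate):
    """Annual rate -> annual probability, 1 - exp(-rate)."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise DomainError("rate must be non-negative")
    p = -np.expm1(-rate)
    return float(p) if p.ndim == 0 else p
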