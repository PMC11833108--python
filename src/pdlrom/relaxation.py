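"""Three-term Prony relaxation function with admissibility constraints.

The dimensionless relaxation function of the generalized Maxwell model is

    G(t) = p1 + p2 e^(-p3 t) + p4 e^(-p5 t) + p6 e^(-p7 t),

with long-term weight p1, branch weights p2, p4, p6 in (0, 1) and decay
rates p3 > p5 > p7 (time constants tau_j = 1/rate, tau1 < tau2 < tau3).
Admissibility for a record sampled every ``t_min`` seconds over
``t_max`` seconds requires the fastest time constant to resolve the
sampling (p3 <= 1/t_min), the slowest to fit inside the record
(p7 >= 1/t_max), the time constants to be separated by at least a
factor ``C`` (default 8, so cross-branch carry-over e^-C ~ 3.4e-4 is
negligible), and the weights to sum to one so that G(0) = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PronySeries",
    "ConstraintReport",
    "relaxation_modulus",
    "validate_constraints",
    "decades_spanned",
    "recommended_terms",
]

#: default minimum ratio between consecutive time constants
DEFAULT_SEPARATION = 8.0

#: tolerance of the weight-sum equality constraint for stored series
WEIGHT_SUM_TOL = 1e-9

#: margin within which a weight counts as "near" its open bound (0, 1)
NEAR_BOUND_MARGIN = 1e-6


@dataclass(frozen=True)
class PronySeries:
    """Weights and rates of the three-branch relaxation function.

    ``p1, p2, p4, p6`` are the dimensionless weights (long-term term
    first), ``p3, p5, p7`` the branch decay rates in 1/s.  ``C`` is the
    minimum separation factor between consecutive time constants used
    when validating.  Construction checks only positivity and the open
    weight bounds; the equality and separation constraints are checked
    by :func:`validate_constraints` so that non-conforming candidates
    can still be represented and reported on.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    C: float = DEFAULT_SEPARATION

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p4", "p6"):
            w = getattr(self, name)
            if not 0.0 < w < 1.0:
                raise ValueError(f"weight {name} must lie in (0, 1)")
        for name in ("p3", "p5", "p7"):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate {name} must be positive")
        if self.C <= 1:
            raise ValueError("separation factor C must exceed 1")

    @classmethod
    def from_taus(cls, p1: float, p2: float, tau1: float, p4: float,
                  tau2: float, p6: float, tau3: float,
                  C: float = DEFAULT_SEPARATION) -> "PronySeries":
        """Construct from time constants tau_j = 1/rate (seconds)."""
        return cls(p1=p1, p2=p2, p3=1.0 / tau1, p4=p4, p5=1.0 / tau2,
                   p6=p6, p7=1.0 / tau3, C=C)

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p4, self.p6])

    @property
    def rates(self) -> np.ndarray:
        """Branch decay rates (fast to slow) in 1/s."""
        return np.array([self.p3, self.p5, self.p7])

    @property
    def branch_weights(self) -> np.ndarray:
        """Weights of the decaying branches (fast to slow)."""
        return np.array([self.p2, self.p4, self.p6])

    @property
    def tau1(self) -> float:
        return 1.0 / self.p3

    @property
    def tau2(self) -> float:
        return 1.0 / self.p5

    @property
    def tau3(self) -> float:
        return 1.0 / self.p7

    def weight_sum(self) -> float:
        return float(self.weights.sum())


def relaxation_modulus(series: PronySeries, t):
    """Evaluate G(t); accepts a scalar or an array of times >= 0.

    G(0) = 1 when the weights satisfy the sum constraint, G is monotone
    non-increasing, and G(inf) = p1.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    g = (series.p1
         + series.p2 * np.exp(-series.p3 * t_arr)
         + series.p4 * np.exp(-series.p5 * t_arr)
         + series.p6 * np.exp(-series.p7 * t_arr))
    return float(g) if np.isscalar(t) or t_arr.ndim == 0 else g


@dataclass(frozen=True)
class ConstraintReport:
    """Per-constraint pass/fail report for a Prony series."""

    weight_sum_ok: bool
    weights_in_bounds: bool
    slowest_rate_ok: bool       # p7 >= 1/t_max (tau3 fits in the record)
    fastest_rate_ok: bool       # p3 <= 1/t_min (tau1 resolves sampling)
    separation_12_ok: bool      # p3/p5 >= C
    separation_23_ok: bool      # p5/p7 >= C
    near_bound_weights: tuple[str, ...] = field(default_factory=tuple)

    @property
    def all_pass(self) -> bool:
        return (self.weight_sum_ok and self.weights_in_bounds
                and self.slowest_rate_ok and self.fastest_rate_ok
                and self.separation_12_ok and self.separation_23_ok)

    def as_dict(self) -> dict[str, bool]:
        return {
            "weight_sum": self.weight_sum_ok,
            "weights_in_bounds": self.weights_in_bounds,
            "slowest_rate": self.slowest_rate_ok,
            "fastest_rate": self.fastest_rate_ok,
            "separation_12": self.separation_12_ok,
            "separation_23": self.separation_23_ok,
        }


def validate_constraints(series: PronySeries, t_min: float,
                         t_max: float) -> ConstraintReport:
    """Check the admissibility constraints against a data window.

    ``t_min`` is the sampling interval and ``t_max`` the record duration
    in seconds.  Returns a report rather than raising: candidate series
    produced during identification may violate constraints and are then
    rejected by the caller.  Weights within 1e-6 of the open bounds
    (0, 1) still pass but are listed in ``near_bound_weights``.
    """
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    weights = {"p1": series.p1, "p2": series.p2,
               "p4": series.p4, "p6": series.p6}
    near = tuple(
        name for name, w in weights.items()
        if w < NEAR_BOUND_MARGIN or w > 1.0 - NEAR_BOUND_MARGIN
    )
    return ConstraintReport(
        weight_sum_ok=abs(series.weight_sum() - 1.0) <= WEIGHT_SUM_TOL,
        weights_in_bounds=all(0.0 < w < 1.0 for w in weights.values()),
        slowest_rate_ok=series.p7 >= 1.0 / t_max,
        fastest_rate_ok=series.p3 <= 1.0 / t_min,
        separation_12_ok=series.p3 / series.p5 >= series.C,
        separation_23_ok=series.p5 / series.p7 >= series.C,
        near_bound_weights=near,
    )


def decades_spanned(t_min: float, t_max: float) -> float:
    """Number of logarithmic decades spanned by the data, lg(t_max/t_min).

    One Prony term per decade is the usual rule of thumb; see
    :func:`recommended_terms`.
    """
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    return math.log10(t_max / t_min)


def recommended_terms(t_min: float, t_max: float) -> int:
    """Recommended number of Prony terms: decade count to the nearest integer.

    A window spanning 3.26 decades is represented with three terms (one
    per decade, fractional remainders below half a decade not adding a
    branch).
    """
    return max(1, round(decades_spanned(t_min, t_max)))
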