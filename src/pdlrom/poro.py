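"""Strain-dependent permeability and Péclet-number regime analysis.

Interstitial fluid in the ligament moves both by pressure-driven bulk
flow (Darcy advection) and by diffusion.  The Péclet number Pe = L v / D
compares the two; writing the velocity as L/t and normalising time by
the viscoelastic relaxation constant tau_v gives

    Pe = (L^2 / (D tau_v)) * (t / tau_v)^(-1),

so Pe * (t/tau_v) = (L / L_d)^2 with the material diffusion length
L_d = sqrt(D tau_v).  Poroelastic (advection-dominated) behaviour
therefore fades as viscoelastic relaxation progresses, with the
transition conventionally placed between t/tau_v = 0.1 and 10.

The permeability of the compressed ligament drops with porosity loss:

    k(lambda) = k0 * (n/n0)^2 * exp(M (lambda - 1))      lambda < 1,
    k(lambda) = k0                                        lambda >= 1,

the tension clamp reflecting that the compressive derivation of the law
has no established tensile counterpart.  The porosity-stretch coupling
uses uniaxial solid-volume conservation, n = 1 - (1 - n0)/lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PermeabilityLaw",
    "DimensionlessSetup",
    "permeability",
    "porosity_from_stretch",
    "peclet",
    "diffusion_length",
    "dimensionless_length",
    "classify_regime",
    "REGIME_BOUNDS",
]

#: normalised-time bounds of the advection-to-diffusion transition
REGIME_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class PermeabilityLaw:
    """Exponential strain-dependent intrinsic permeability.

    ``k0`` is the intrinsic permeability (m^2) and ``n0`` the porosity
    at the reference state lambda = 1; ``M`` is the dimensionless decay
    exponent.
    """

    k0: float
    n0: float
    M: float

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if not 0 < self.n0 < 1:
            raise ValueError("n0 must lie in (0, 1)")
        if self.M <= 0:
            raise ValueError("M must be positive")


@dataclass(frozen=True)
class DimensionlessSetup:
    """Characteristic scales of a poro-viscoelastic experiment.

    ``L``: characteristic length in m (e.g. ligament width ~1e-4 m);
    ``D``: apparent mass diffusion coefficient in m^2/s;
    ``tau_v``: viscoelastic relaxation time constant in s.
    """

    L: float
    D: float
    tau_v: float

    def __post_init__(self) -> None:
        if self.L <= 0 or self.D < 0 or self.tau_v <= 0:
            raise ValueError("need L > 0, D >= 0, tau_v > 0")


def porosity_from_stretch(law: PermeabilityLaw, l):
    """Porosity n(lambda) = 1 - (1 - n0)/lambda (solid volume conserved).

    Valid for uniaxial volume change J = lambda; the pore space is
    exhausted at lambda = 1 - n0.
    """
    l_arr = np.asarray(l, dtype=float)
    if np.any(l_arr <= 1.0 - law.n0):
        raise ValueError("stretch must exceed 1 - n0 (porosity > 0)")
    return 1.0 - (1.0 - law.n0) / l_arr


def permeability(law: PermeabilityLaw, l):
    """Intrinsic permeability k(lambda) in m^2.

    Constant ``k0`` in tension (lambda >= 1), the exponential
    porosity-squared law in compression; continuous at lambda = 1.
    """
    l_arr = np.asarray(l, dtype=float)
    n = porosity_from_stretch(law, l_arr)
    k = law.k0 * (n / law.n0) ** 2 * np.exp(law.M * (l_arr - 1.0))
    k = np.where(l_arr >= 1.0, law.k0, k)
    return float(k) if np.isscalar(l) or l_arr.ndim == 0 else k


def peclet(setup: DimensionlessSetup, t_over_tau):
    """Péclet number as a function of normalised time t/tau_v.

    Pe = (L^2 / (D tau_v)) / (t/tau_v); strictly decreasing, so
    advection dominance (Pe >> 1) is an early-time phenomenon.
    """
    t_arr = np.asarray(t_over_tau, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("t_over_tau must be positive")
    pe = dimensionless_length(setup) / t_arr
    return float(pe) if np.isscalar(t_over_tau) or t_arr.ndim == 0 else pe


def diffusion_length(setup: DimensionlessSetup) -> float:
    """Material diffusion length L_d = sqrt(D tau_v) in m.

    The distance covered by diffusion within one viscoelastic relaxation
    time.
    """
    return float(np.sqrt(setup.D * setup.tau_v))


def dimensionless_length(setup: DimensionlessSetup) -> float:
    """(L / L_d)^2 = L^2 / (D tau_v), the setup's dimensionless length.

    Equals Pe * (t/tau_v) for every time.
    """
    return setup.L**2 / (setup.D * setup.tau_v)


def classify_regime(t_over_tau: float,
                    bounds: tuple[float, float] = REGIME_BOUNDS) -> str:
    """Transport-regime label at normalised time t/tau_v.

    Advection (poroelastic flow) dominates before ``bounds[0]``,
    diffusion after ``bounds[1]`` (viscoelastic relaxation then being
    essentially complete), with a transition in between (boundaries
    inclusive).
    """
    if t_over_tau <= 0:
        raise ValueError("t_over_tau must be positive")
    lo, hi = bounds
    if t_over_tau < lo:
        return "advection-dominated (poroelastic)"
    if t_over_tau > hi:
        return "diffusion-dominated (viscoelastic relaxation complete)"
    return "transition"
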