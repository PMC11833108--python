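"""One-term Storåkers (hyperfoam) compressible hyperelasticity.

The strain energy density, per unit reference volume and in MPa, is

    U = (2 mu / alpha^2) [ l1^a + l2^a + l3^a - 3
                           + (1/beta) (J^(-a*b) - 1) ],   J = l1 l2 l3,

with shear-modulus scale ``mu`` (MPa), stretch exponent ``alpha`` and
compressibility coefficient ``beta``; the effective Poisson's ratio is
``nu = beta / (1 + 2 beta)``.  The process is taken as isothermal, so
the thermal volume split is inert (J_th = 1, elastic stretches equal
total stretches).

Under uniaxial nominal stress with free lateral faces the transverse
stretches relax to ``l^(-nu)`` and the axial nominal (first
Piola-Kirchhoff) stress has the closed form implemented in
:func:`uniaxial_stress`.  The measured actuator force/displacement pair
is mapped onto this stress/strain law through the proportional mapping
``(sigma, eps) = (p8 F, p9 x)``; because crown loading strains the
ligament in both tension and compression, the model force is the mean
of the tensile and (absolute) compressive branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HyperfoamParams",
    "StressStrainMapping",
    "beta_from_nu",
    "nu_from_beta",
    "strain_energy",
    "transverse_stretch",
    "uniaxial_stress",
    "initial_moduli",
    "force_from_displacement",
]


def beta_from_nu(nu: float) -> float:
    """Compressibility coefficient beta = nu / (1 - 2 nu)."""
    if not 0 < nu < 0.5:
        raise ValueError("nu must lie in (0, 0.5)")
    return nu / (1.0 - 2.0 * nu)


def nu_from_beta(beta: float) -> float:
    """Effective Poisson's ratio nu = beta / (1 + 2 beta)."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return beta / (1.0 + 2.0 * beta)


@dataclass(frozen=True)
class HyperfoamParams:
    """Material parameters of the one-term compressible hyperelastic law.

    Attributes
    ----------
    mu
        Shear-modulus scale in MPa; equals the initial shear modulus.
    alpha
        Dimensionless stretch exponent (controls stress-strain
        progressivity).
    beta
        Dimensionless compressibility coefficient; related to the
        effective Poisson's ratio by ``beta = nu / (1 - 2 nu)``.

    Only the single-term law is supported; a multi-term sum would add
    (mu_i, alpha_i, beta_i) triples with mu_0 = sum(mu_i).
    """

    mu: float
    alpha: float
    beta: float

    n_terms = 1

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @classmethod
    def from_poisson(cls, mu: float, alpha: float, nu: float) -> "HyperfoamParams":
        """Construct from (mu, alpha, nu) with beta derived."""
        return cls(mu=mu, alpha=alpha, beta=beta_from_nu(nu))

    @property
    def nu(self) -> float:
        """Effective Poisson's ratio."""
        return nu_from_beta(self.beta)


@dataclass(frozen=True)
class StressStrainMapping:
    """Proportional force/displacement -> stress/strain mapping.

    ``p8`` scales force to stress (MPa/N), ``p9`` scales displacement to
    strain (1/mm): sigma = p8 * F, eps = p9 * x.  The mapping is specific
    to one load condition and specimen geometry.
    """

    p8: float
    p9: float

    def __post_init__(self) -> None:
        if self.p8 <= 0 or self.p9 <= 0:
            raise ValueError("p8 and p9 must be positive")


def _check_stretches(*stretches) -> None:
    for l in stretches:
        if np.any(np.asarray(l) <= 0):
            raise ValueError("principal stretches must be positive")


def strain_energy(params: HyperfoamParams, l1, l2, l3):
    """Strain energy density U(l1, l2, l3) in MPa.

    Symmetric in its stretch arguments (isotropy) and zero at the
    reference state (1, 1, 1).
    """
    _check_stretches(l1, l2, l3)
    l1, l2, l3 = (np.asarray(l, dtype=float) for l in (l1, l2, l3))
    a, b = params.alpha, params.beta
    jac = l1 * l2 * l3
    dev = l1**a + l2**a + l3**a - 3.0
    vol = (jac ** (-a * b) - 1.0) / b
    return 2.0 * params.mu / a**2 * (dev + vol)


def transverse_stretch(params: HyperfoamParams, l_axial):
    """Transverse stretch l_axial^(-nu) under uniaxial nominal stress.

    This is the lateral stretch that makes the transverse stress vanish
    (dU/dl2 = 0 with l2 = l3); the resulting volume ratio is
    J = l_axial^(1/(1+2*beta)).
    """
    _check_stretches(l_axial)
    return np.asarray(l_axial, dtype=float) ** (-params.nu)


def uniaxial_stress(params: HyperfoamParams, l):
    """Uniaxial nominal (first Piola-Kirchhoff) stress in MPa.

    sigma(l) = (2 mu / alpha) (1 - l^(-alpha (1+3 beta)/(1+2 beta)))
               * l^(alpha - 1)

    which equals dU/dl1 evaluated at the laterally relaxed state
    l2 = l3 = l^(-nu).
    """
    _check_stretches(l)
    l = np.asarray(l, dtype=float)
    a, b = params.alpha, params.beta
    expo = a * (1.0 + 3.0 * b) / (1.0 + 2.0 * b)
    return 2.0 * params.mu / a * (1.0 - l ** (-expo)) * l ** (a - 1.0)


def initial_moduli(params: HyperfoamParams) -> dict[str, float]:
    """Initial (small-strain) moduli in MPa.

    Returns shear ``G0 = mu``, bulk ``K0 = 2 mu (1/3 + beta)`` and the
    uniaxial nominal-stress slope ``E0 = 2 mu (1 + nu)`` at l = 1.
    """
    mu, b = params.mu, params.beta
    return {
        "G0": mu,
        "K0": 2.0 * mu * (1.0 / 3.0 + b),
        "E0": 2.0 * mu * (1.0 + params.nu),
    }


def force_from_displacement(params: HyperfoamParams,
                            mapping: StressStrainMapping, x):
    """Elastic actuator force F(x) in N for displacement x in mm.

    The displacement is mapped to a tension and a compression stretch
    ``l = 1 +/- p9 x`` and the force is the average of the tensile and
    absolute compressive contribution:

        F(x) = ( sigma(1 + p9 x) + |sigma(1 - p9 x)| ) / (2 p8).

    Even in x by construction; negative inputs are folded to |x|.

    Raises
    ------
    ValueError
        If ``p9 |x| >= 1`` (the compressive stretch would be <= 0).
    """
    x = np.abs(np.asarray(x, dtype=float))
    eps = mapping.p9 * x
    if np.any(eps >= 1.0):
        raise ValueError("p9 * |x| must stay below 1 (compression limit)")
    f_tension = uniaxial_stress(params, 1.0 + eps) / mapping.p8
    f_compression = uniaxial_stress(params, 1.0 - eps) / mapping.p8
    return 0.5 * (f_tension + np.abs(f_compression))
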