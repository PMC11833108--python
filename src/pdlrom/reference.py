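"""Reference parameter values for the porcine premolar specimen.

These are the published identification results that accompany the
packaged test campaign (:func:`pdlrom.protocols.builtin_test_table`):
the constitutive parameters of the ligament's hyperfoam law, the
per-test visco-hyperelastic fits of the twelve valid records, the joint
all-tests fit of the augmented model, the ligament permeability law, and
poroelastic constants of the surrounding hard tissues (reference
metadata only — no field solver consumes them here).

Units follow the package convention: s, mm, N, MPa; permeability m^2.
"""

from __future__ import annotations

import pandas as pd

from .hyperelastic import HyperfoamParams, StressStrainMapping
from .poro import PermeabilityLaw
from .relaxation import PronySeries
from .rom import RomParams

__all__ = [
    "REFERENCE_CONSTITUTIVE",
    "reference_hyperfoam",
    "individual_fit_table",
    "individual_fit_params",
    "campaign_fit_params",
    "REFERENCE_PERMEABILITY",
    "HARD_TISSUE_POROELASTIC",
]

#: constitutive parameters identified for the specimen (mu in MPa)
REFERENCE_CONSTITUTIVE = {"mu": 0.0338, "alpha": 29.7, "nu": 0.236}


def reference_hyperfoam() -> HyperfoamParams:
    """Hyperfoam parameters identified for the specimen."""
    c = REFERENCE_CONSTITUTIVE
    return HyperfoamParams.from_poisson(mu=c["mu"], alpha=c["alpha"], nu=c["nu"])


# Per-test fits (product-form model, constitutive parameters frozen at
# REFERENCE_CONSTITUTIVE) of the twelve valid campaign records, in the
# published order: 0.1 mm tests (odd ids) first, then 0.2 mm (even ids).
# Columns: p1 p2 tau1 p4 tau2 p6 tau3 (relaxation), p8 p9 (mapping), r2.
_INDIVIDUAL_FITS = [
    (3, 0.245, 0.315, 2.73, 0.139, 28.8, 0.301, 383.0, 0.0158, 1.177, 0.994),
    (5, 0.324, 0.419, 6.51, 0.102, 52.1, 0.155, 832.0, 0.0101, 0.853, 0.997),
    (7, 0.371, 0.259, 1.41, 0.286, 11.3, 0.084, 163.0, 0.0187, 1.108, 0.994),
    (9, 0.376, 0.211, 2.17, 0.317, 32.0, 0.096, 830.0, 0.0189, 0.937, 0.994),
    (11, 0.304, 0.304, 0.46, 0.192, 10.2, 0.199, 854.0, 0.0189, 0.937, 0.994),
    (2, 0.354, 0.194, 3.27, 0.129, 33.3, 0.323, 371.0, 0.0020, 0.516, 0.988),
    (4, 0.419, 0.152, 5.88, 0.113, 47.0, 0.316, 419.0, 0.0066, 0.715, 0.999),
    (6, 0.424, 0.191, 3.62, 0.116, 29.4, 0.269, 360.0, 0.0058, 0.665, 0.999),
    (8, 0.366, 0.328, 2.02, 0.108, 32.0, 0.197, 417.0, 0.0092, 0.779, 0.996),
    (10, 0.468, 0.151, 2.87, 0.145, 27.4, 0.237, 342.0, 0.0100, 0.717, 0.997),
    (12, 0.352, 0.207, 12.3, 0.145, 98.1, 0.295, 1171.0, 0.0117, 0.733, 0.999),
    (14, 0.338, 0.366, 6.86, 0.102, 70.2, 0.194, 562.0, 0.0101, 0.749, 0.997),
]

_FIT_COLUMNS = ["test", "p1", "p2", "tau1", "p4", "tau2", "p6", "tau3",
                "p8", "p9", "r2"]


def individual_fit_table() -> pd.DataFrame:
    """Per-test fit results of the twelve valid records as a DataFrame."""
    return pd.DataFrame(_INDIVIDUAL_FITS, columns=_FIT_COLUMNS)


def individual_fit_params(test_id: int) -> RomParams:
    """Model parameters of one per-test fit (no rate/history terms).

    The published weights are rounded to three decimals and can sum to
    0.999-1.001; they are renormalized here so the stored series
    satisfies the weight-sum equality exactly.
    """
    row = next((r for r in _INDIVIDUAL_FITS if r[0] == test_id), None)
    if row is None:
        raise KeyError(f"no per-test fit for test {test_id}")
    _, p1, p2, tau1, p4, tau2, p6, tau3, p8, p9, _r2 = row
    total = p1 + p2 + p4 + p6
    return RomParams(
        hyper=reference_hyperfoam(),
        mapping=StressStrainMapping(p8=p8, p9=p9),
        prony=PronySeries.from_taus(p1 / total, p2 / total, tau1,
                                    p4 / total, tau2, p6 / total, tau3),
        p10=0.0,
        p11=1.0,
    )


def campaign_fit_params() -> RomParams:
    """Joint all-tests fit of the augmented model (with rate term).

    Relaxation weights 0.320/0.275/0.160/0.245 with time constants
    4.52/39.1/387 s, mapping p8 = 0.0182 MPa/N, p9 = 0.889 1/mm, rate
    term p10 = 22.9 N/mm with e-folding ramp time 12.6 s.
    """
    return RomParams(
        hyper=reference_hyperfoam(),
        mapping=StressStrainMapping(p8=0.0182, p9=0.889),
        prony=PronySeries.from_taus(0.320, 0.275, 4.52, 0.160, 39.1,
                                    0.245, 387.0),
        p10=22.9,
        p11=1.0 / 12.6,
    )


#: ligament permeability law (reference porosity measured by fluid
#: expression under compression)
REFERENCE_PERMEABILITY = PermeabilityLaw(k0=8.81e-15, n0=0.70, M=14.2)

#: poroelastic constants of the surrounding hard tissues (E in GPa,
#: permeability in m^2); reference metadata only
HARD_TISSUE_POROELASTIC = {
    "cortical_bone": {"E_GPa": 14.58, "nu": 0.325, "k_m2": 1.47e-20, "n": 0.05},
    "cancellous_bone": {"E_GPa": 0.41, "nu": 0.3, "k_m2": 1.0e-9, "n": 0.8},
    "alveolar_bone": {"E_GPa": 0.345, "nu": 0.31, "k_m2": 5.29e-14, "n": 0.8},
    "tooth": {"E_GPa": 15.0, "nu": 0.31, "k_m2": 3.88e-17, "n": 0.05},
}
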