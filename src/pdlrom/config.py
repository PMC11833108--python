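"""Parameter (de)serialization to the YAML/JSON config schema.

Keys carry their units: mu_MPa, alpha, nu, p8_MPa_per_N, p9_per_mm for
the backbone and mapping; p1, p2, p4, p6 with tau1_s..tau3_s (rates
derived) and C for the relaxation function; p10_N_per_mm and tau_H_s
for the rate term; k0_m2, n0, M and L_m, D_m2_per_s, tau_v_s for the
poroelastic quantities.
"""

from __future__ import annotations

import yaml

from .hyperelastic import HyperfoamParams, StressStrainMapping
from .poro import DimensionlessSetup, PermeabilityLaw
from .relaxation import DEFAULT_SEPARATION, PronySeries
from .rom import RomParams

__all__ = ["rom_params_to_dict", "rom_params_from_dict",
           "save_rom_params", "load_rom_params",
           "permeability_from_dict", "dimensionless_from_dict"]


def rom_params_to_dict(params: RomParams) -> dict:
    pr = params.prony
    return {
        "mu_MPa": params.hyper.mu,
        "alpha": params.hyper.alpha,
        "nu": params.hyper.nu,
        "p8_MPa_per_N": params.mapping.p8,
        "p9_per_mm": params.mapping.p9,
        "p1": pr.p1, "p2": pr.p2, "p4": pr.p4, "p6": pr.p6,
        "tau1_s": pr.tau1, "tau2_s": pr.tau2, "tau3_s": pr.tau3,
        "C": pr.C,
        "p10_N_per_mm": params.p10,
        "tau_H_s": params.tau_rate,
    }


def rom_params_from_dict(payload: dict) -> RomParams:
    return RomParams(
        hyper=HyperfoamParams.from_poisson(
            mu=float(payload["mu_MPa"]),
            alpha=float(payload["alpha"]),
            nu=float(payload["nu"])),
        mapping=StressStrainMapping(p8=float(payload["p8_MPa_per_N"]),
                                    p9=float(payload["p9_per_mm"])),
        prony=PronySeries.from_taus(
            float(payload["p1"]), float(payload["p2"]), float(payload["tau1_s"]),
            float(payload["p4"]), float(payload["tau2_s"]),
            float(payload["p6"]), float(payload["tau3_s"]),
            C=float(payload.get("C", DEFAULT_SEPARATION))),
        p10=float(payload.get("p10_N_per_mm", 0.0)),
        p11=1.0 / float(payload.get("tau_H_s", 1.0)),
    )


def save_rom_params(params: RomParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(rom_params_to_dict(params), fh, sort_keys=False)


def load_rom_params(path) -> RomParams:
    with open(path, encoding="utf-8") as fh:
        return rom_params_from_dict(yaml.safe_load(fh))


def permeability_from_dict(payload: dict) -> PermeabilityLaw:
    return PermeabilityLaw(k0=float(payload["k0_m2"]),
                           n0=float(payload["n0"]),
                           M=float(payload["M"]))


def dimensionless_from_dict(payload: dict) -> DimensionlessSetup:
    return DimensionlessSetup(L=float(payload["L_m"]),
                              D=float(payload["D_m2_per_s"]),
                              tau_v=float(payload["tau_v_s"]))
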