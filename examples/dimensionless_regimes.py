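"""Péclet-number regime analysis and strain-dependent permeability.

For the ligament in situ (width ~0.1 mm, soft-tissue apparent diffusion
coefficient 1e-9 m^2/s, relaxation time ~10 s) the Péclet number falls
below one around a normalised time of one: pressure-driven pore flow
dominates only the early response and fades as viscoelastic relaxation
progresses.  The second table shows how compression shuts down the
ligament's permeability.
"""

import numpy as np

from pdlrom import (DimensionlessSetup, classify_regime, diffusion_length,
                    peclet, permeability)
from pdlrom.reference import REFERENCE_PERMEABILITY

setup = DimensionlessSetup(L=1e-4, D=1e-9, tau_v=10.0)
print(f"diffusion length L_d = {diffusion_length(setup) * 1e3:.2f} mm "
      f"(equals the ligament width: Pe(t/tau_v = 1) = 1)")
print(f"{'t/tau_v':>9} {'Pe':>10}  regime")
for t in (0.01, 0.1, 1.0, 10.0, 100.0):
    print(f"{t:9.2f} {peclet(setup, t):10.3g}  {classify_regime(t)}")

print("\npermeability of the compressed ligament (k0 = 8.81e-15 m^2):")
print(f"{'stretch':>8} {'k [m^2]':>10}")
for stretch in (1.2, 1.0, 0.95, 0.9, 0.8):
    print(f"{stretch:8.2f} {permeability(REFERENCE_PERMEABILITY, stretch):10.3g}")
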