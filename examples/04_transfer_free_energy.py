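"""Transfer free energies from Γ(m) and their difference between two states.

Given preferential interaction parameters across cosolvent concentrations,
the chemical-potential derivative −Γ·RT·(M_p/M_c)·(1/m + ∂lnγ/∂m) is
integrated from pure water to each concentration.  The U−N difference is
the cosolvent's effect on the folding free energy (negative = denaturing).
"""

import numpy as np

from solvkb.kbi import (
    ActivityModel,
    Gamma,
    GammaSeries,
    delta_transfer,
    transfer_free_energy,
)

T = 298.15          # K
M_p = 7500.0        # g/mol, a small protein
M_c = 60.06         # g/mol, urea

m = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0])  # mol/L
# synthetic Γ series: the U state accumulates more cosolvent than N
series_N = GammaSeries("N", [Gamma(1.0 * mi, 0.05, 12.0, 3e-4, "N", mi) for mi in m])
series_U = GammaSeries("U", [Gamma(2.2 * mi, 0.08, 12.0, 3e-4, "U", mi) for mi in m])

activity = ActivityModel.ideal()
curve_N = transfer_free_energy(series_N, activity, T, M_p, M_c)
curve_U = transfer_free_energy(series_U, activity, T, M_p, M_c)
delta = delta_transfer(curve_U, curve_N)

print("m_c (mol/L)   Δμ_tr^N     Δμ_tr^U     δΔμ^U−N  (kcal/mol)")
for mi in (0.2, 0.5, 1.0):
    print(f"  {mi:4.1f}      {curve_N.at(mi):+9.3f}  {curve_U.at(mi):+9.3f}"
          f"  {delta.at(mi):+9.3f}")
print("negative δΔμ^U−N: the cosolvent lowers the unfolding free energy,")
print("i.e. it destabilizes the native state at every concentration shown")

# the M_p/M_c prefactor is a convention choice; the molal variant drops it
curve_N_molal = transfer_free_energy(series_N, activity, T, M_p, M_c,
                                     include_mass_ratio=False)
print(f"molal convention (no M_p/M_c): Δμ_tr^N(1 M) = "
      f"{curve_N_molal.at(1.0):+.4f} kcal/mol "
      f"(vs {curve_N.at(1.0):+.3f} with the mass ratio)")
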