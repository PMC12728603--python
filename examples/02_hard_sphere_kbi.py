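"""Kirkwood–Buff integral of a hard-sphere solute: the analytic benchmark.

A solute that only excludes solvent from a sphere of radius a has
G = −(4/3)πa³ — pure excluded volume.  The distance-resolved KBI should
plateau at that value once R passes the sphere radius.
"""

import numpy as np

from solvkb import accumulate_mddf, kbi_profile
from solvkb.synthetic import GeneratorSpec, HardCore, SpeciesSpec, generate
from solvkb.units import mol_per_L_to_per_A3

a = 3.0  # Å
spec = GeneratorSpec(
    species=(SpeciesSpec("w", mol_per_L_to_per_A3(33.3), profile=HardCore(a)),),
    box=(30.0, 30.0, 30.0),
    n_frames=200,
    seed=6,
)
frames, truth = generate(spec)
result = accumulate_mddf(frames, "w", bin_width=0.1, cutoff=8.0,
                         oversample=40, seed=1, d_bulk=10.0)
profile = kbi_profile(result, n_blocks=10)

expected = -(4.0 / 3.0) * np.pi * a**3
print(f"analytic excluded volume: {expected:.3f} Å³")
print(f"generator ground truth:   {truth.G['w']:.3f} ± {truth.G_error['w']:.3f} Å³")
print(f"measured plateau G:       {profile.plateau:.3f} ± {profile.plateau_se:.3f} Å³"
      f"  ({profile.plateau_L_per_mol:.5f} L/mol)")
print("agreement within the quoted error bars validates the full chain")
print("from minimum distances through the finite-volume KBI")
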