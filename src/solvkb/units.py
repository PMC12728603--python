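"""Physical constants and unit conversions.

Conventions used throughout the package: lengths in Å, energies in kcal/mol,
temperatures in K, molar masses in g/mol.  Number densities are molecules/Å³
internally; helpers convert to and from mol/L.  Kirkwood–Buff integrals are
kept in Å³/molecule and additionally reported in L/mol.
"""

#: Gas constant in kcal mol⁻¹ K⁻¹.
R_GAS_KCAL: float = 1.987204e-3

#: Avogadro constant, mol⁻¹ (2019 SI exact value).
AVOGADRO: float = 6.02214076e23

#: Conversion factor: 1 Å³/molecule = 6.02214076e-4 L/mol.
A3_PER_MOLECULE_TO_L_PER_MOL: float = 6.02214076e-4

#: Conversion factor: 1 mol/L = 6.02214076e-4 molecules/Å³.
MOL_PER_L_TO_PER_A3: float = 6.02214076e-4


def mol_per_L_to_per_A3(c: float) -> float:
    """Convert a molar concentration (mol/L) to a number density (molecules/Å³)."""
    return c * MOL_PER_L_TO_PER_A3


def per_A3_to_mol_per_L(rho: float) -> float:
    """Convert a number density (molecules/Å³) to a molar concentration (mol/L)."""
    return rho / MOL_PER_L_TO_PER_A3
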