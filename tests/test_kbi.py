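"""Kirkwood–Buff integrals, Γ, Wyman linkage and transfer free energies."""

import numpy as np
import pytest

from solvkb import accumulate_mddf
from solvkb.errors import IncompatibilityError
from solvkb.kbi import (
    ActivityModel,
    Gamma,
    GammaSeries,
    KBIProfile,
    delta_transfer,
    gamma,
    kbi_profile,
    transfer_free_energy,
    wyman_delta,
)
from solvkb.synthetic import GeneratorSpec, SpeciesSpec, StepProfile, generate
from solvkb.units import A3_PER_MOLECULE_TO_L_PER_MOL, R_GAS_KCAL, mol_per_L_to_per_A3


def test_kbi_ideal_solvent_plateau_is_zero(ideal_gas_run):
    _, _, res = ideal_gas_run
    prof = kbi_profile(res, n_blocks=10)
    assert abs(prof.plateau) < 3 * prof.plateau_se


def test_kbi_hard_sphere_excluded_volume(hard_sphere_run):
    """A 3 Å hard-sphere solute plants G = −(4/3)π·3³ = −113.097 Å³."""
    _, _, res = hard_sphere_run
    prof = kbi_profile(res, n_blocks=10)
    expected = -(4.0 / 3.0) * np.pi * 27.0
    assert abs(prof.plateau - expected) < 3 * prof.plateau_se
    # inside the core G(R) is the swept ideal volume: strictly negative
    assert prof.G[0] <= 0.0
    # unit conversion is wired through
    assert np.isclose(prof.plateau_L_per_mol,
                      prof.plateau * A3_PER_MOLECULE_TO_L_PER_MOL)


def test_kbi_step_enhancement_matches_shell_volume_oracle():
    """g = 2 on [3,5) Å: plateau G equals Σ (g−1)·V_shell from ideal counts."""
    spec = GeneratorSpec(
        species=(SpeciesSpec("w", mol_per_L_to_per_A3(33.3),
                             profile=StepProfile(3.0, 5.0, 2.0)),),
        box=(30.0,) * 3, n_frames=150, seed=14,
    )
    frames, _ = generate(spec)
    res = accumulate_mddf(frames, "w", bin_width=0.1, cutoff=10.0, oversample=40,
                          seed=9, d_bulk=10.0)
    # plateau window [6, 10] sits beyond the planted step (which ends at 5)
    prof = kbi_profile(res, plateau_window=4.0, n_blocks=10)
    centers = res.r
    g_bin = np.where((centers >= 3.0) & (centers < 5.0), 2.0, 1.0)
    shell_volumes = res.box_volume * res.ideal_frac
    oracle = float(np.sum((g_bin - 1.0) * shell_volumes))
    assert abs(prof.plateau - oracle) < 3 * prof.plateau_se


def test_kbi_identity_with_mddf_histogram(hard_sphere_run):
    """G from cumulative counts ≡ Σ (mddf−1)·ideal/ρ (same histograms)."""
    _, _, res = hard_sphere_run
    prof = kbi_profile(res)
    alt = np.cumsum((res.mddf - 1.0) * res.histogram.ideal_counts) / res.bulk_density
    np.testing.assert_allclose(prof.G, alt, atol=1e-10)


def _profile(G_value, rho, species="c", n=10):
    R = np.linspace(1, 10, n)
    G = np.full(n, float(G_value))
    return KBIProfile(R, G, species, rho, float(G_value), (5.0, 10.0), 0.0, 0.0)


def test_gamma_zero_when_profiles_equal():
    pc = _profile(4.0, 0.5)
    pw = _profile(4.0, 0.5, species="w")
    assert gamma(pc, pw).value == 0.0


def test_gamma_arithmetic_in_L_per_mol():
    """G_pc = +5 L/mol, G_pw = −1 L/mol at ρ_c = 0.5 mol/L gives Γ = 3."""
    to_A3 = 1.0 / A3_PER_MOLECULE_TO_L_PER_MOL
    pc = _profile(5.0 * to_A3, mol_per_L_to_per_A3(0.5))
    pw = _profile(-1.0 * to_A3, mol_per_L_to_per_A3(0.5), species="w")
    assert np.isclose(gamma(pc, pw).value, 3.0)


def test_gamma_grid_mismatch():
    pc = _profile(1.0, 0.5, n=10)
    pw = _profile(1.0, 0.5, n=12)
    with pytest.raises(IncompatibilityError):
        gamma(pc, pw)


def test_gamma_species_label_exchange_negates(hard_sphere_run):
    """Swapping which species is 'cosolvent' flips Γ up to the ρ factor."""
    _, _, res = hard_sphere_run
    prof = kbi_profile(res)
    flat = _profile(0.0, prof.rho, species="x")
    flat.R = prof.R.copy()
    flat.G = np.zeros_like(prof.G)
    g_ab = gamma(prof, flat, R=prof.R[-1])
    g_ba = gamma(flat, prof, R=prof.R[-1])
    # same rho here, so the exchange negates exactly
    assert np.isclose(g_ab.value, -g_ba.value)


def test_wyman_delta_values_and_antisymmetry():
    gU = Gamma(3.0, 0.2, 12.0, 3e-4)
    gN = Gamma(1.0, 0.2, 12.0, 3e-4)
    d = wyman_delta(gU, gN)
    assert np.isclose(d.value, 2.0)
    assert np.isclose(d.error, np.hypot(0.2, 0.2))
    assert "denatured" in d.interpretation
    rev = wyman_delta(gN, gU)
    assert rev.value == -d.value
    assert wyman_delta(gU, gU).value == 0.0


def _series(state, m, values, err=0.0):
    return GammaSeries(state, [Gamma(v, err, 12.0, 3e-4, state, mi)
                               for mi, v in zip(m, values)])


def test_transfer_zero_gamma_gives_zero_curve():
    m = np.linspace(0.1, 1.0, 7)
    cur = transfer_free_energy(_series("N", m, np.zeros(7)),
                               ActivityModel.ideal(), 298.15, 9000.0, 60.06)
    assert cur.dmu[0] == 0.0
    assert np.abs(cur.dmu).max() == 0.0


def test_transfer_linear_gamma_closed_form():
    """Γ = c·m with ideal activity integrates to −c·R·T·(Mp/Mc)·m exactly."""
    T, Mp, Mc, c = 298.15, 9000.0, 60.06, 1.7
    m = np.linspace(0.1, 1.0, 7)
    cur = transfer_free_energy(_series("N", m, c * m), ActivityModel.ideal(),
                               T, Mp, Mc)
    exact = -c * R_GAS_KCAL * T * (Mp / Mc)
    for mi in (0.25, 0.5, 1.0):
        assert abs(cur.at(mi) - exact * mi) <= 1e-9 * abs(exact * mi)
    assert cur.dmu[0] == 0.0


def test_transfer_quadratic_gamma_closed_form():
    """Γ = c·m² integrates to −(c/2)·R·T·(Mp/Mc)·m² to 1e-6 at 1000 nodes."""
    T, Mp, Mc, c = 298.15, 9000.0, 60.06, 0.8
    m = np.linspace(0.0, 1.0, 1000)[1:]
    cur = transfer_free_energy(_series("U", m, c * m * m), ActivityModel.ideal(),
                               T, Mp, Mc, n_nodes=1000)
    exact = -(c / 2.0) * R_GAS_KCAL * T * (Mp / Mc)
    assert abs(cur.at(1.0) - exact) <= 1e-6 * abs(exact)


def test_transfer_scales_linearly_in_temperature():
    m = np.linspace(0.1, 1.0, 5)
    s = _series("N", m, 1.3 * m)
    c300 = transfer_free_energy(s, ActivityModel.ideal(), 300.0, 9000.0, 60.06)
    c600 = transfer_free_energy(s, ActivityModel.ideal(), 600.0, 9000.0, 60.06)
    np.testing.assert_allclose(c600.dmu, 2.0 * c300.dmu, rtol=1e-12)


def test_transfer_input_validation():
    with pytest.raises(ValueError):
        transfer_free_energy(_series("N", [0.0, 0.5], [0.0, 1.0]),
                             ActivityModel.ideal(), 300.0, 9000.0, 60.0)
    with pytest.raises(ValueError):
        transfer_free_energy(_series("N", [0.5, 0.2], [1.0, 2.0]),
                             ActivityModel.ideal(), 300.0, 9000.0, 60.0)
    with pytest.raises(ValueError):
        transfer_free_energy(_series("N", [0.5], [1.0]),
                             ActivityModel.ideal(), 300.0, 9000.0, 60.0)


def test_activity_model_from_table(tmp_path):
    m = np.linspace(0.1, 1.0, 10)
    lng = 0.1 * m * m
    p = tmp_path / "act.dat"
    np.savetxt(p, np.column_stack([m, lng]), header="m ln_gamma")
    act = ActivityModel.from_table(p)
    # central-difference derivative of 0.1 m² is 0.2 m (exact for quadratics)
    np.testing.assert_allclose(act.dlng_dm(np.array([0.5])), [0.1], atol=1e-12)
    with pytest.raises(ValueError):
        ActivityModel(np.array([0.2, 0.1]), np.array([0.0, 0.0]))


def test_delta_transfer_difference_and_cycle():
    m = np.linspace(0.1, 1.0, 7)
    act = ActivityModel.ideal()
    T, Mp, Mc = 298.15, 9000.0, 60.06
    scale = R_GAS_KCAL * T * Mp / Mc
    # linear-Γ curves engineered to Δμ_U = −2m, Δμ_N = −m (kcal/mol)
    cU = transfer_free_energy(_series("U", m, (2.0 / scale) * m), act, T, Mp, Mc)
    cN = transfer_free_energy(_series("N", m, (1.0 / scale) * m), act, T, Mp, Mc)
    d = delta_transfer(cU, cN)
    assert abs(d.at(1.0) - (-1.0)) < 1e-9
    # identical curves give zero, and the cycle closes
    same = delta_transfer(cU, cU)
    assert np.abs(same.delta_dmu).max() == 0.0
    rev = delta_transfer(cN, cU)
    np.testing.assert_allclose(d.delta_dmu + rev.delta_dmu, 0.0, atol=1e-15)


def test_delta_transfer_grid_and_temperature_mismatch():
    m = np.linspace(0.1, 1.0, 5)
    act = ActivityModel.ideal()
    a = transfer_free_energy(_series("U", m, m), act, 300.0, 9000.0, 60.0)
    b = transfer_free_energy(_series("N", m, m), act, 310.0, 9000.0, 60.0)
    with pytest.raises(IncompatibilityError):
        delta_transfer(a, b)
    c = transfer_free_energy(_series("N", m[:-1], m[:-1]), act, 300.0, 9000.0, 60.0)
    with pytest.raises(IncompatibilityError):
        delta_transfer(a, c)
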