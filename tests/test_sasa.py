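"""Shrake–Rupley SASA and the additive transfer-model m-value."""

import numpy as np
import pytest

from solvkb.errors import SolvKBError
from solvkb.sasa import (
    CoefficientTable,
    load_radii,
    mvalue_additive,
    partition_sasa,
    shrake_rupley,
)

from conftest import make_atom


def sphere_area(r):
    return 4.0 * np.pi * r * r


def test_isolated_sphere_exact():
    a = make_atom(element="C")
    res = shrake_rupley([a], probe=1.4, n_points=960, radii={"C": 1.6})
    assert res.total == pytest.approx(sphere_area(3.0), abs=0.0)
    assert res.total_nm2 == pytest.approx(res.total / 100.0)


def test_distant_spheres_unoccluded():
    r, probe = 1.6, 1.4
    far = 2 * (r + probe) + 0.5
    atoms = [make_atom(1, xyz=(0, 0, 0)), make_atom(2, xyz=(far, 0, 0))]
    res = shrake_rupley(atoms, probe=probe, n_points=960, radii={"C": r})
    np.testing.assert_allclose(res.atom_areas, sphere_area(r + probe))


def test_two_sphere_overlap_matches_spherical_caps():
    """Two unit-radius atoms 1 Å apart: accessible area from cap geometry."""
    probe = 1.4
    atoms = [make_atom(1, xyz=(0, 0, 0)), make_atom(2, xyz=(1.0, 0, 0))]
    res = shrake_rupley(atoms, probe=probe, n_points=4000, radii={"C": 1.0})
    R, d = 1.0 + probe, 1.0
    x = d / 2.0  # plane of intersection (equal radii)
    cap_height = R - x
    exact = sphere_area(R) - 2.0 * np.pi * R * cap_height
    for area in res.atom_areas:
        assert abs(area - exact) / exact < 0.01


def test_point_count_convergence(alanine_dipeptide):
    atoms, _ = alanine_dipeptide
    coarse = shrake_rupley(atoms, n_points=960)
    fine = shrake_rupley(atoms, n_points=4000)
    assert abs(fine.total - coarse.total) / fine.total < 0.02


def test_rigid_motion_invariance(alanine_dipeptide):
    """Areas are invariant to rigid motion up to the lattice-orientation bound."""
    from scipy.spatial.transform import Rotation

    atoms, _ = alanine_dipeptide
    base = shrake_rupley(atoms, n_points=960)
    rng = np.random.default_rng(17)
    rot = Rotation.random(random_state=rng)
    xyz = np.array([[a.x, a.y, a.z] for a in atoms])
    moved_xyz = rot.apply(xyz) + np.array([5.0, -3.0, 11.0])
    moved = [
        make_atom(a.serial, a.name, a.residue_name, a.residue_index, a.chain,
                  tuple(p), a.element)
        for a, p in zip(atoms, moved_xyz)
    ]
    res = shrake_rupley(moved, n_points=960)
    assert abs(res.total - base.total) / base.total < 0.005


def test_unknown_element_fails_loudly():
    a = make_atom(element="ZZ")
    with pytest.raises(SolvKBError, match="ZZ"):
        shrake_rupley([a])


def test_default_radii_table_loads():
    radii = load_radii()
    assert radii["C"] == 1.70 and radii["O"] == 1.52


def test_partition_classes_match_hand_labels(alanine_dipeptide):
    atoms, labels = alanine_dipeptide
    res = shrake_rupley(atoms, n_points=960)
    part = partition_sasa(res)
    # per-residue conservation, exact
    for row in part.itertuples():
        by_res = [a for a, _ in zip(atoms, res.atom_areas)
                  if a.residue_index == row.residue_index]
        assert row.total_A2 == pytest.approx(row.backbone_A2 + row.sidechain_A2,
                                             abs=0.0)
    # hand-labelled class assignment
    expected_bb = sum(ar for a, ar, lbl in zip(atoms, res.atom_areas, labels)
                      if lbl == "backbone")
    assert part["backbone_A2"].sum() == pytest.approx(expected_bb, abs=1e-12)
    # the all-backbone glycine residue has zero side-chain area
    gly = part[part.residue_name == "GLY"].iloc[0]
    assert gly.sidechain_A2 == 0.0


def test_mvalue_identity_is_zero(alanine_dipeptide):
    atoms, _ = alanine_dipeptide
    res = shrake_rupley(atoms, n_points=240)
    table = CoefficientTable.packaged_synthetic()
    est = mvalue_additive(res, res, table)
    assert est.m_value == 0.0
    assert est.backbone_contribution + est.sidechain_contribution == est.m_value


def test_mvalue_single_group_arithmetic():
    """A_U/A_ref = 2, A_N/A_ref = 1 with Δg = 100 cal/mol gives +0.1 kcal/mol/M."""
    aN = [make_atom(1, name="CA", element="C")]
    sN = shrake_rupley(aN, probe=1.4, n_points=960, radii={"C": 1.6})
    # pick radii so that the U-state single sphere has exactly double the area
    rU = np.sqrt(2.0) * 3.0 - 1.4
    sU = shrake_rupley(aN, probe=1.4, n_points=960, radii={"C": rU})
    # rescale reference so A_N / a_ref = 1 exactly; the zero-coefficient ALA
    # side-chain group satisfies the coverage requirement without contributing
    table = CoefficientTable({"backbone": 100.0, "ALA": 0.0},
                             {"backbone": sN.total, "ALA": 50.0})
    est = mvalue_additive(sN, sU, table)
    assert est.m_value == pytest.approx(0.1, rel=1e-12)


def test_mvalue_matches_independent_summation(alanine_dipeptide):
    """Full estimate equals a spreadsheet-style oracle over groups, 1e-12."""
    atoms, _ = alanine_dipeptide
    rng = np.random.default_rng(23)
    # denatured copy: same composition, displaced side chain geometry
    moved = [
        make_atom(a.serial, a.name, a.residue_name, a.residue_index, a.chain,
                  (a.x + rng.normal(scale=1.0), a.y, a.z), a.element)
        for a in atoms
    ]
    sN = shrake_rupley(atoms, n_points=240)
    sU = shrake_rupley(moved, n_points=240)
    table = CoefficientTable.packaged_synthetic()
    est = mvalue_additive(sN, sU, table)

    def oracle(sasa):
        part = partition_sasa(sasa)
        total = (part["backbone_A2"].sum() / table.a_ref["backbone"]
                 * table.dg["backbone"] / 1000.0)
        for row in part.itertuples():
            total += (row.sidechain_A2 / table.a_ref[row.residue_name]
                      * table.dg[row.residue_name] / 1000.0)
        return total

    assert est.m_value == pytest.approx(oracle(sU) - oracle(sN), abs=1e-12)
    assert (est.backbone_contribution + est.sidechain_contribution
            == pytest.approx(est.m_value, abs=1e-15))


def test_mvalue_composition_mismatch_lists_residues(alanine_dipeptide):
    atoms, _ = alanine_dipeptide
    sN = shrake_rupley(atoms, n_points=60)
    other = [make_atom(1, "CA", "TRP", 1, "A", (0, 0, 0), "C")]
    sO = shrake_rupley(other, n_points=60)
    with pytest.raises(SolvKBError, match="TRP"):
        mvalue_additive(sN, sO, CoefficientTable.packaged_synthetic())


def test_against_independent_sasa_implementation(alanine_dipeptide):
    """Cross-check against mdtraj's Shrake–Rupley on the same radii."""
    mdtraj = pytest.importorskip("mdtraj")

    atoms, _ = alanine_dipeptide
    top = mdtraj.Topology()
    chain = top.add_chain()
    res_map = {}
    for a in atoms:
        if a.residue_index not in res_map:
            res_map[a.residue_index] = top.add_residue(a.residue_name, chain)
        top.add_atom(a.name, mdtraj.element.get_by_symbol(a.element), res_map[a.residue_index])
    xyz = np.array([[[a.x, a.y, a.z] for a in atoms]]) / 10.0  # Å -> nm
    traj = mdtraj.Trajectory(xyz, top)
    ref = mdtraj.shrake_rupley(traj, probe_radius=0.14, n_sphere_points=960).sum() * 100.0
    mine = shrake_rupley(atoms, probe=1.4, n_points=960).total
    assert abs(mine - ref) / ref < 0.03
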