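"""MDDF accumulation, normalization and group decompositions."""

import numpy as np
import pytest
from scipy.integrate import quad

import solvkb as sk
from solvkb import Configuration, SolventSpecies
from solvkb.errors import EmptyInputError, IncompatibilityError, PartitionError
from solvkb.mddf import accumulate_mddf, decompose, differential_density_map
from solvkb.synthetic import GaussianBump, GeneratorSpec, SpeciesSpec, generate
from solvkb.units import mol_per_L_to_per_A3


def test_binning_convention_half_open():
    """A distance of exactly 2.03 Å lands in the [2.00, 2.05) bin."""
    fr = Configuration(np.array([[15.0, 15, 15]]),
                       [SolventSpecies("c", 1, [[17.03, 15, 15]])], (30,) * 3)
    res = accumulate_mddf([fr], "c", bin_width=0.05, cutoff=5.0, oversample=5,
                          seed=0)
    i = int(np.floor(2.03 / 0.05))
    assert res.histogram.real_counts[i] == 1.0
    assert np.isclose(res.edges[i], 2.00) and np.isclose(res.edges[i + 1], 2.05)
    assert res.histogram.real_counts.sum() == 1.0


def test_zero_frames_rejected():
    with pytest.raises(EmptyInputError):
        accumulate_mddf([], "c")


def test_ideal_gas_normalization(ideal_gas_run):
    """For g ≡ 1 frames the MDDF is 1 within sampling error in sampled bins."""
    _, _, res = ideal_gas_run
    hist = res.histogram
    sampled = hist.ideal_counts * hist.n_frames >= 25
    se = hist.real_per_frame.std(axis=0, ddof=1) / np.sqrt(hist.n_frames)
    se_mddf = se[sampled] / hist.ideal_counts[sampled]
    z = (res.mddf[sampled] - 1.0) / se_mddf
    assert np.abs(z).max() < 3.0
    # and the mean over sampled bins is even tighter
    assert abs(res.mddf[sampled].mean() - 1.0) < 3 * se_mddf.mean() / np.sqrt(sampled.sum())


def test_planted_profile_recovery():
    """Frames drawn with g(r) = 1 + exp(−(r−2)²/0.08) give back that profile."""
    g = GaussianBump(1.0, 2.0, 0.2)
    spec = GeneratorSpec(
        species=(SpeciesSpec("w", mol_per_L_to_per_A3(33.3), profile=g),),
        box=(24.0,) * 3, n_frames=200, seed=7,
    )
    frames, _ = generate(spec)
    res = accumulate_mddf(frames, "w", bin_width=0.1, cutoff=6.0, oversample=20,
                          seed=7, d_bulk=8.0)
    hist = res.histogram
    edges = res.edges
    # exact bin-averaged expectation of the planted profile (shell-weighted)
    expected = np.array([
        quad(lambda r: g(r) * r * r, edges[i], edges[i + 1])[0]
        / quad(lambda r: r * r, edges[i], edges[i + 1])[0]
        for i in range(hist.n_bins)
    ])
    well_sampled = hist.ideal_counts * hist.n_frames >= 50
    se = hist.real_per_frame.std(axis=0, ddof=1) / np.sqrt(hist.n_frames)
    z = (res.mddf[well_sampled] - expected[well_sampled]) / (
        se[well_sampled] / hist.ideal_counts[well_sampled]
    )
    assert np.abs(z).max() < 3.0


def test_oversample_convergence(ideal_gas_run):
    """Doubling the ideal oversampling moves the MDDF by less than the
    real-count sampling error."""
    frames, _, res10 = ideal_gas_run
    res40 = accumulate_mddf(frames, "w", bin_width=0.5, cutoff=10.0,
                            oversample=40, seed=3, d_bulk=8.0)
    hist = res10.histogram
    sampled = hist.ideal_counts * hist.n_frames >= 25
    se = hist.real_per_frame.std(axis=0, ddof=1) / np.sqrt(hist.n_frames)
    se_mddf = se[sampled] / hist.ideal_counts[sampled]
    assert np.all(np.abs(res40.mddf[sampled] - res10.mddf[sampled]) < se_mddf)


# ---------------------------------------------------------------------------
# decompositions
# ---------------------------------------------------------------------------

def _chain_run(enhanced=(), seed=3, n_frames=40):
    """Hand-built frames around a 10-bead chain; ``enhanced`` residues get
    double the solvent molecules placed at 1.2 Å from their bead.

    The shell radius stays below half the 3 Å bead spacing so every molecule
    is attributed to its own bead."""
    rng = np.random.default_rng(seed)
    box = np.array([40.0, 40.0, 40.0])
    solute = np.column_stack([np.linspace(6, 33, 10), np.full(10, 20.0),
                              np.full(10, 20.0)])
    frames = []
    for f in range(n_frames):
        pts = []
        for bead in range(10):
            k = 4 if bead in enhanced else 2
            for _ in range(k):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                pts.append(solute[bead] + 1.2 * u)
        frames.append(Configuration(
            solute, [SolventSpecies("c", 1, np.array(pts))], box, frame_id=f))
    return frames, solute


def test_decompose_conservation_and_trivial_groups():
    frames, solute = _chain_run(seed=12)
    res = accumulate_mddf(frames, "c", bin_width=0.25, cutoff=8.0, oversample=10,
                          seed=5, density_mode="total")
    one_group = decompose(res, {i: "all" for i in range(len(solute))})
    np.testing.assert_allclose(one_group.groups["all"], res.mddf,
                               rtol=0, atol=1e-12)
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 3, len(solute))
    dec = decompose(res, {i: int(g) for i, g in enumerate(labels)})
    assert np.abs(dec.total() - res.mddf).max() < 1e-12
    with pytest.raises(PartitionError):
        decompose(res, {0: "a"})


def test_decompose_unrealized_group_is_zero():
    """A group whose atoms never realize a minimum contributes nothing."""
    # solvent clustered at bead 0 only; far beads never realize a minimum
    rng = np.random.default_rng(4)
    solute = np.array([[10.0, 20, 20], [30.0, 20, 20]])
    pts = solute[0] + rng.normal(scale=0.8, size=(30, 3))
    fr = Configuration(solute, [SolventSpecies("c", 1, pts)], (40,) * 3)
    res = accumulate_mddf([fr], "c", bin_width=0.25, cutoff=8.0, oversample=5,
                          seed=1, density_mode="total")
    dec = decompose(res, {0: "A", 1: "B"})
    assert np.all(dec.groups["B"] == 0.0)
    np.testing.assert_array_equal(dec.groups["A"], res.mddf)


def test_differential_map_identity_and_doubling():
    frames, solute = _chain_run(seed=8)
    res = accumulate_mddf(frames, "c", bin_width=0.25, cutoff=8.0, oversample=10,
                          seed=2, density_mode="total")
    part = {i: i for i in range(len(solute))}
    dec = decompose(res, part)
    self_map = differential_density_map(dec, dec)
    assert max(np.abs(v).max() for v in self_map.diff.values()) == 0.0
    # doubling one residue's contribution in B makes that row -1x A's row
    import copy
    dec_b = copy.deepcopy(dec)
    dec_b.groups[3] = 2.0 * dec_b.groups[3]
    dmap = differential_density_map(dec, dec_b)
    np.testing.assert_allclose(dmap.diff[3], -dec.groups[3], atol=1e-15)
    assert max(np.abs(dmap.diff[j]).max() for j in part.values() if j != 3) == 0.0


def test_differential_map_recovers_planted_residues():
    """Two states differing on residues {3, 7} show up as the top-2 summary."""
    frames_a, solute = _chain_run(enhanced=(), seed=21)
    frames_b, _ = _chain_run(enhanced=(3, 7), seed=22)
    part = {i: i for i in range(len(solute))}
    kw = dict(bin_width=0.25, cutoff=8.0, oversample=10, density_mode="total")
    dec_a = decompose(accumulate_mddf(frames_a, "c", seed=31, **kw), part)
    dec_b = decompose(accumulate_mddf(frames_b, "c", seed=32, **kw), part)
    dmap = differential_density_map(dec_b, dec_a)
    summary = dmap.summary(window=(0.0, 5.0))
    top2 = sorted(summary, key=lambda g: abs(summary[g]), reverse=True)[:2]
    assert set(top2) == {3, 7}


def test_differential_map_grid_mismatch():
    frames, solute = _chain_run(seed=5, n_frames=5)
    part = {i: "x" for i in range(len(solute))}
    a = decompose(accumulate_mddf(frames, "c", bin_width=0.25, cutoff=8.0,
                                  oversample=5, seed=1, density_mode="total"), part)
    b = decompose(accumulate_mddf(frames, "c", bin_width=0.5, cutoff=8.0,
                                  oversample=5, seed=1, density_mode="total"), part)
    with pytest.raises(IncompatibilityError):
        differential_density_map(a, b)
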