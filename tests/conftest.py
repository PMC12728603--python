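"""Shared fixtures: synthetic runs and small structure builders."""

from __future__ import annotations

import numpy as np
import pytest

from solvkb import accumulate_mddf
from solvkb.io import AtomRecord
from solvkb.synthetic import GeneratorSpec, HardCore, SpeciesSpec, generate
from solvkb.units import mol_per_L_to_per_A3


def make_atom(serial=1, name="CA", resname="ALA", resindex=1, chain="A",
              xyz=(0.0, 0.0, 0.0), element="C") -> AtomRecord:
    return AtomRecord(serial, name, resname, resindex, chain, *xyz, element)


@pytest.fixture(scope="session")
def ideal_gas_run():
    """200 frames of a structureless (g ≡ 1) single-species fluid + its MDDF."""
    spec = GeneratorSpec(
        species=(SpeciesSpec("w", mol_per_L_to_per_A3(33.3)),),
        box=(24.0, 24.0, 24.0),
        n_frames=200,
        seed=11,
    )
    frames, truth = generate(spec)
    result = accumulate_mddf(frames, "w", bin_width=0.5, cutoff=10.0,
                             oversample=20, seed=2, d_bulk=8.0)
    return frames, truth, result


@pytest.fixture(scope="session")
def hard_sphere_run():
    """Hard-sphere solute (a = 3 Å), ideal fluid outside, 200 frames + MDDF."""
    spec = GeneratorSpec(
        species=(SpeciesSpec("w", mol_per_L_to_per_A3(33.3),
                             profile=HardCore(3.0)),),
        box=(30.0, 30.0, 30.0),
        n_frames=200,
        seed=6,
    )
    frames, truth = generate(spec)
    result = accumulate_mddf(frames, "w", bin_width=0.1, cutoff=8.0,
                             oversample=40, seed=1, d_bulk=10.0)
    return frames, truth, result


@pytest.fixture
def alanine_dipeptide():
    """A small blocked-alanine-like fixture with hand-assigned atom classes.

    Coordinates are a plausible rigid geometry (not an energy minimum); the
    point is a realistic mix of backbone and side-chain atom names.
    """
    atoms = [
        # (name, resname, resindex, xyz, element, expected class)
        ("N", "ALA", 1, (0.00, 0.00, 0.00), "N", "backbone"),
        ("H", "ALA", 1, (-0.50, -0.85, 0.20), "H", "backbone"),
        ("CA", "ALA", 1, (1.45, 0.00, 0.00), "C", "backbone"),
        ("HA", "ALA", 1, (1.80, -1.02, 0.15), "H", "backbone"),
        ("CB", "ALA", 1, (2.00, 0.90, 1.10), "C", "sidechain"),
        ("HB1", "ALA", 1, (1.70, 1.93, 0.95), "H", "sidechain"),
        ("HB2", "ALA", 1, (3.09, 0.85, 1.10), "H", "sidechain"),
        ("HB3", "ALA", 1, (1.65, 0.55, 2.07), "H", "sidechain"),
        ("C", "ALA", 1, (2.00, 0.55, -1.30), "C", "backbone"),
        ("O", "ALA", 1, (1.40, 1.40, -1.95), "O", "backbone"),
        ("N", "GLY", 2, (3.20, 0.05, -1.65), "N", "backbone"),
        ("H", "GLY", 2, (3.65, -0.65, -1.10), "H", "backbone"),
        ("CA", "GLY", 2, (3.90, 0.50, -2.85), "C", "backbone"),
        ("HA2", "GLY", 2, (3.40, 1.35, -3.30), "H", "backbone"),
        ("HA3", "GLY", 2, (4.92, 0.80, -2.60), "H", "backbone"),
        ("C", "GLY", 2, (3.95, -0.60, -3.90), "C", "backbone"),
        ("O", "GLY", 2, (3.50, -1.72, -3.65), "O", "backbone"),
        ("OXT", "GLY", 2, (4.45, -0.35, -5.00), "O", "backbone"),
    ]
    records = [
        make_atom(i + 1, name, resname, resindex, "A", xyz, element)
        for i, (name, resname, resindex, xyz, element, _) in enumerate(atoms)
    ]
    labels = [cls for *_, cls in atoms]
    return records, labels


def brute_force_min_distances(solute: np.ndarray, solvent: np.ndarray,
                              box: np.ndarray, apm: int):
    """Independent O(N_solute × N_atoms) double-loop oracle."""
    n_mol = len(solvent) // apm
    out = []
    for m in range(n_mol):
        best = (np.inf, -1, -1)
        for p in range(len(solute)):
            for a in range(apm):
                d = solvent[m * apm + a] - solute[p]
                d = d - box * np.round(d / box)
                r = np.sqrt((d * d).sum())
                if r < best[0]:
                    best = (r, p, a)
        out.append(best)
    return out
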