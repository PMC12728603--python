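"""Minimum solute–solvent distances under the periodic minimum-image convention.

For every solvent molecule the engine reports the smallest distance between
any of its atoms and any solute atom, together with the atom pair realizing
it.  This minimum distance is the reaction coordinate of the whole solvation
analysis: distribution functions, Kirkwood–Buff integrals and preferential
interactions are all built from these events.

The kernel is an exact, vectorised all-pairs computation; ties on equal
distances are broken towards the lowest (solute_atom_index,
solvent_atom_index) pair, which is the first occurrence in row-major order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import EmptySpeciesError
from .io import Configuration, SolventSpecies

__all__ = ["MinDistEvent", "MinDistEvents", "min_distances", "ideal_min_distances"]

# cap on the size of the (solute x solvent-atom) distance block held in memory
_CHUNK_ENTRIES = 4_000_000


@dataclass(frozen=True)
class MinDistEvent:
    """Minimum distance of one solvent molecule to the solute."""

    molecule_index: int
    distance: float
    solute_atom_index: int
    solvent_atom_index: int


class MinDistEvents:
    """Column-oriented container of minimum-distance events.

    Behaves like a sequence of :class:`MinDistEvent` but stores the fields as
    numpy arrays (``distance``, ``molecule_index``, ``solute_atom_index``,
    ``solvent_atom_index``) for histogramming.
    """

    def __init__(self, molecule_index, distance, solute_atom_index, solvent_atom_index):
        self.molecule_index = np.asarray(molecule_index, dtype=np.intp)
        self.distance = np.asarray(distance, dtype=float)
        self.solute_atom_index = np.asarray(solute_atom_index, dtype=np.intp)
        self.solvent_atom_index = np.asarray(solvent_atom_index, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.distance)

    def __getitem__(self, i: int) -> MinDistEvent:
        return MinDistEvent(
            int(self.molecule_index[i]),
            float(self.distance[i]),
            int(self.solute_atom_index[i]),
            int(self.solvent_atom_index[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MinDistEvents(n={len(self)})"


def _minimum_image_distances(solute: np.ndarray, atoms: np.ndarray,
                             box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distances, shape (n_solute, n_atoms)."""
    d = atoms[None, :, :] - solute[:, None, :]
    d -= box * np.round(d / box)
    return np.sqrt((d * d).sum(axis=-1))


def _min_events_for_atoms(solute: np.ndarray, atoms: np.ndarray, box: np.ndarray,
                          apm: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-molecule minima over contiguous apm-blocks of ``atoms``.

    Returns (distance, solute_atom_index, solvent_atom_index) arrays, one
    entry per molecule, tie-broken to the lowest index pair.
    """
    n_mol = len(atoms) // apm
    n_solute = len(solute)
    out_d = np.empty(n_mol)
    out_p = np.empty(n_mol, dtype=np.intp)
    out_s = np.empty(n_mol, dtype=np.intp)
    mols_per_chunk = max(1, _CHUNK_ENTRIES // max(1, n_solute * apm))
    for start in range(0, n_mol, mols_per_chunk):
        stop = min(start + mols_per_chunk, n_mol)
        block = atoms[start * apm : stop * apm]
        dist = _minimum_image_distances(solute, block, box)
        # (n_solute, n_block_mol, apm) -> (n_block_mol, n_solute*apm); row-major
        # flattening scans solute index first, then solvent atom: argmin's
        # first-occurrence rule therefore implements the documented tie-break.
        d3 = dist.reshape(n_solute, stop - start, apm).transpose(1, 0, 2)
        flat = d3.reshape(stop - start, n_solute * apm)
        idx = np.argmin(flat, axis=1)
        rows = np.arange(stop - start)
        out_d[start:stop] = flat[rows, idx]
        out_p[start:stop] = idx // apm
        out_s[start:stop] = idx % apm
    return out_d, out_p, out_s


def _check_half_box(solute: np.ndarray, box: np.ndarray) -> None:
    if len(solute) < 2:
        return
    span = solute.max(axis=0) - solute.min(axis=0)
    if np.any(span > box / 2):
        warnings.warn(
            "solute extends beyond half the box in at least one dimension; "
            "minimum-image distances may be ambiguous",
            stacklevel=3,
        )


def min_distances(frame: Configuration, species: str,
                  heavy_only: bool = False) -> MinDistEvents:
    """Minimum distance of every molecule of ``species`` to the solute.

    All atoms (hydrogens included) participate by default.  ``heavy_only``
    restricts the solute side to non-hydrogen atoms (requires the frame to
    carry AtomRecord metadata; solvent species are flat coordinate blocks, so
    to exclude solvent hydrogens supply a species without them).  Exactly one
    event per molecule is returned.
    """
    sp = frame.species(species)
    if sp.n_molecules == 0:
        raise EmptySpeciesError(f"species {species!r} has zero molecules")
    solute = frame.solute_xyz
    if heavy_only:
        atoms = frame.solute_atoms
        if atoms is not None:
            keep = [i for i, a in enumerate(atoms) if a.element.upper() != "H"]
            solute = solute[keep]
    _check_half_box(solute, frame.box)
    d, p, s = _min_events_for_atoms(solute, sp.coordinates, frame.box,
                                    sp.atoms_per_molecule)
    return MinDistEvents(np.arange(sp.n_molecules), d, p, s)


def _unwrapped_templates(sp: SolventSpecies, box: np.ndarray) -> np.ndarray:
    """Molecule conformations relative to their first atom, PBC-unwrapped."""
    mols = sp.molecules()
    rel = mols - mols[:, :1, :]
    rel -= box * np.round(rel / box)
    return rel


def ideal_min_distances(frame: Configuration, species: str, oversample: int = 10,
                        seed: int | np.random.Generator = 0) -> MinDistEvents:
    """Minimum distances for the numerically generated ideal (non-interacting)
    reference state.

    ``oversample × n_molecules`` rigid-body placements are generated: each
    draws a molecule conformation uniformly (with replacement) from the real
    molecules of the species, a uniform random rotation (uniform unit
    quaternion) and a uniform random position of its first atom in the box.
    The reference thereby carries the exact shapes of solute and solvent but
    none of their interactions.  Reproducible for a given seed.
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    sp = frame.species(species)
    if sp.n_molecules == 0:
        raise EmptySpeciesError(f"species {species!r} has zero molecules")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_place = oversample * sp.n_molecules
    apm = sp.atoms_per_molecule
    pos = rng.uniform(0.0, 1.0, size=(n_place, 3)) * frame.box
    if apm == 1:
        atoms = pos
    else:
        templates = _unwrapped_templates(sp, frame.box)
        choice = rng.integers(0, sp.n_molecules, size=n_place)
        rel = templates[choice]  # (n_place, apm, 3)
        mats = Rotation.random(n_place, random_state=rng).as_matrix()
        atoms = np.einsum("mij,maj->mai", mats, rel) + pos[:, None, :]
        atoms = atoms.reshape(n_place * apm, 3)
    solute = frame.solute_xyz
    d, p, s = _min_events_for_atoms(solute, atoms, frame.box, apm)
    return MinDistEvents(np.arange(n_place), d, p, s)
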