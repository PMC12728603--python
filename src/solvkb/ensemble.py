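"""Conformational-ensemble bookkeeping.

Fraction of native contacts Q, optimal-superposition RMSD (Kabsch),
representative-structure selection and Boltzmann population free energies.
Contact maps are inputs (pair list plus native Cα–Cα distances); a helper
derives the native distances from a supplied native structure.  Q follows
the upper-bound criterion: a contact counts as formed when its Cα distance
does not exceed the native distance by more than the tolerance (default 20%).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import SolvKBError
from .units import R_GAS_KCAL

__all__ = [
    "ContactMap",
    "EnsembleState",
    "fraction_native_contacts",
    "kabsch_rmsd",
    "superpose",
    "representative_structure",
    "boltzmann_dg",
]


@dataclass
class ContactMap:
    """Native residue-pair contacts with their native Cα–Cα distances."""

    pairs: np.ndarray             # (n, 2) 0-based residue indices, i < j
    distances: np.ndarray         # (n,) Å

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)
        if len(self.pairs) != len(self.distances):
            raise SolvKBError("pairs and distances length mismatch")
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise SolvKBError("contact pairs must satisfy i < j")
        seen = {tuple(p) for p in self.pairs}
        if len(seen) != len(self.pairs):
            raise SolvKBError("duplicate contact pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def validated(cls, pairs, distances, min_seq_sep: int = 3) -> "ContactMap":
        cmap = cls(pairs, distances)
        sep = cmap.pairs[:, 1] - cmap.pairs[:, 0]
        if np.any(sep < min_seq_sep):
            raise SolvKBError(
                f"contacts closer than {min_seq_sep} residues in sequence"
            )
        return cmap

    @classmethod
    def from_file(cls, path: str | Path, min_seq_sep: int = 3) -> "ContactMap":
        """Three-column text file: i, j, native Cα–Cα distance (Å)."""
        data = np.loadtxt(path, comments="#", ndmin=2)
        return cls.validated(data[:, :2].astype(int), data[:, 2], min_seq_sep)

    @classmethod
    def from_native(cls, pairs, ca_coords: np.ndarray,
                    min_seq_sep: int = 3) -> "ContactMap":
        """Derive native distances for a given pair list from Cα coordinates."""
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        ca = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
        d = np.linalg.norm(ca[pairs[:, 0]] - ca[pairs[:, 1]], axis=1)
        return cls.validated(pairs, d, min_seq_sep)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# i j d_native_A\n")
            for (i, j), d in zip(self.pairs, self.distances):
                fh.write(f"{i} {j} {d:.17g}\n")


@dataclass
class EnsembleState:
    """A labelled set of member structures (Cα coordinates) with populations."""

    label: str
    members: list[np.ndarray]
    mean_q: float = float("nan")

    @property
    def population(self) -> int:
        return len(self.members)


def fraction_native_contacts(ca_coords: np.ndarray, cmap: ContactMap,
                             tolerance: float = 0.20) -> float:
    """Fraction of contacts whose Cα distance ≤ (1 + tolerance) × native.

    A contact is native when the distance in the query structure does not
    exceed the native distance by more than ``tolerance`` (default 20%).
    """
    if len(cmap) == 0:
        raise SolvKBError("empty contact map")
    ca = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
    if cmap.pairs.max() >= len(ca):
        raise SolvKBError("structure does not cover all contact-map residues")
    d = np.linalg.norm(ca[cmap.pairs[:, 0]] - ca[cmap.pairs[:, 1]], axis=1)
    formed = d <= (1.0 + tolerance) * cmap.distances
    return float(np.count_nonzero(formed) / len(cmap))


def _as_coords(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a.reshape(-1, 3)


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    Proper rotations only (determinant +1).  Returns the transformed copy.
    """
    mobile = _as_coords(mobile)
    target = _as_coords(target)
    if mobile.shape != target.shape:
        raise SolvKBError(f"coordinate shape mismatch {mobile.shape} vs {target.shape}")
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    rot, _ = Rotation.align_vectors(tc, mc)
    return rot.apply(mc) + target.mean(axis=0)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal RMSD of two equal-size coordinate sets over rotation+translation."""
    a = _as_coords(a)
    b = _as_coords(b)
    if a.shape != b.shape:
        raise SolvKBError(f"coordinate shape mismatch {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise SolvKBError("need at least 3 atoms for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc)
    # explicit residual: accurate near zero, where the solver's reported
    # rssd loses half the significant digits to cancellation
    diff = rot.apply(bc) - ac
    return float(np.sqrt((diff * diff).sum() / len(a)))


def representative_structure(members: Sequence[np.ndarray]) -> int:
    """Index of the member with minimum RMSD to the ensemble average.

    All members are superposed onto member 0, the coordinate-wise mean is
    taken, and each member's optimal-superposition RMSD to that mean is
    evaluated; ties return the lowest index.  A single alignment pass is
    used (no iterative mean refinement).
    """
    members = [_as_coords(m) for m in members]
    if not members:
        raise SolvKBError("need at least one member")
    if len(members) == 1:
        return 0
    aligned = [members[0]] + [superpose(m, members[0]) for m in members[1:]]
    mean = np.mean(aligned, axis=0)
    rmsds = [kabsch_rmsd(m, mean) for m in members]
    return int(np.argmin(rmsds))


def boltzmann_dg(p_a: float, p_b: float, T: float) -> float:
    """Free-energy difference ΔG = −R·T·ln(p_a/p_b) from state populations.

    A state twice as populated as another lies roughly 0.4 kcal/mol below it
    at 300 K.
    """
    if p_a <= 0 or p_b <= 0:
        raise SolvKBError("populations must be positive")
    if T <= 0:
        raise SolvKBError("temperature must be positive")
    return float(-R_GAS_KCAL * T * np.log(p_a / p_b))
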