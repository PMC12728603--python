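"""Minimum-distance distribution functions (MDDFs).

The MDDF is the density of solvent molecules as a function of the minimum
distance r between any of their atoms and any solute atom, normalized by the
equivalent density in an ideal (non-interacting) system of the same bulk
density:

    MDDF(r) = n_s(r) / n_s*(r)

The ideal reference cannot be written in closed form for solutes and solvents
of general shape, so it is generated numerically by random rigid-body
placements of the real molecules (see
:func:`solvkb.mindist.ideal_min_distances`).  Ideal counts are referenced to
the *bulk* solvent density: the raw placement histogram estimates the volume
fraction of the box at each minimum distance, which is then multiplied by
ρ_s·V.  This makes MDDF → 1 in the bulk and makes the finite-volume
Kirkwood–Buff integral built on the same histograms converge to the true
excess volume independently of the box size (an equal-total-count reference
would bias the integral by the volume fraction already swept at R).

Every real event is attributed to the solute atom realizing the minimum, so
the total MDDF decomposes exactly into per-atom / per-residue /
backbone–side-chain contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    IncompatibilityError,
    InvalidDensityError,
    PartitionError,
)
from .io import AtomRecord, Configuration, DEFAULT_BACKBONE_ATOMS
from .mindist import ideal_min_distances, min_distances

__all__ = [
    "Histogram",
    "MDDFResult",
    "DecomposedMDDF",
    "DifferentialMap",
    "accumulate_mddf",
    "decompose",
    "differential_density_map",
    "residue_partition",
    "backbone_sidechain_partition",
]


@dataclass
class Histogram:
    """Left-closed, half-open minimum-distance histogram, averaged per frame."""

    bin_width: float
    n_bins: int
    real_counts: np.ndarray       # mean real count per frame per bin
    ideal_counts: np.ndarray      # bulk-density-referenced ideal count per bin
    n_frames: int
    real_per_frame: np.ndarray = field(repr=False, default=None)  # (F, B)

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class MDDFResult:
    """MDDF with cumulative counts and per-solute-atom attribution."""

    histogram: Histogram
    mddf: np.ndarray              # real/ideal, 0 where undefined (see mask)
    defined: np.ndarray           # bool mask: ideal_counts > 0
    cum_real: np.ndarray          # N_ps(R) at right bin edges
    cum_ideal: np.ndarray         # N_ps*(R) at right bin edges (bulk reference)
    contributions: np.ndarray     # (n_solute_atoms, n_bins) mean real counts
    species: str
    bulk_density: float           # rho_s, molecules/Å³
    box_volume: float             # mean box volume, Å³
    n_molecules_mean: float
    ideal_frac: np.ndarray        # P(ideal placement falls in bin)
    far_real_per_frame: np.ndarray  # molecules beyond d_bulk, per frame
    far_ideal_frac: float         # P(ideal placement beyond d_bulk)
    params: dict = field(default_factory=dict)

    @property
    def edges(self) -> np.ndarray:
        return self.histogram.edges

    @property
    def r(self) -> np.ndarray:
        return self.histogram.centers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_left_A": self.edges[:-1],
                "r_right_A": self.edges[1:],
                "real_count_per_frame": self.histogram.real_counts,
                "ideal_count_per_frame": self.histogram.ideal_counts,
                "mddf": self.mddf,
                "defined": self.defined.astype(int),
                "cum_real_N": self.cum_real,
                "cum_ideal_Nstar": self.cum_ideal,
            }
        )

    @property
    def metadata(self) -> dict:
        md = {
            "result": "MDDF",
            "species": self.species,
            "bulk_density_per_A3": f"{self.bulk_density:.17g}",
            "box_volume_A3": f"{self.box_volume:.17g}",
            "n_frames": self.histogram.n_frames,
            "n_molecules_mean": f"{self.n_molecules_mean:.17g}",
        }
        md.update({k: str(v) for k, v in self.params.items()})
        return md


def _bulk_density(total_far: float, far_ideal_frac: float, n_frames: int,
                  volume: float, n_mol_mean: float, mode: str) -> float:
    """Bulk-density estimator: far-region molecules over far-region volume.

    Falls back to total N/V when the bulk region is empty (tiny boxes).
    """
    if mode == "total":
        return n_mol_mean / volume
    far_per_frame = total_far / n_frames
    if far_ideal_frac > 0 and far_per_frame > 0:
        return far_per_frame / (far_ideal_frac * volume)
    warnings.warn("bulk region empty; falling back to total N/V density")
    return n_mol_mean / volume


def accumulate_mddf(
    frames: Sequence[Configuration],
    species: str,
    bin_width: float = 0.05,
    cutoff: float = 20.0,
    oversample: int = 10,
    seed: int = 0,
    d_bulk: float = 10.0,
    density_mode: str = "bulk",
) -> MDDFResult:
    """Accumulate minimum-distance histograms over ``frames`` and normalize.

    The ideal reference is regenerated per frame (box fluctuations are
    respected) with ``oversample × n_molecules`` placements; bins are
    half-open ``[i·w, (i+1)·w)`` and a distance exactly at the cutoff is
    excluded.  ``density_mode`` selects the bulk estimator (molecules beyond
    ``d_bulk`` over the matching ideal volume fraction; default) or the total
    N/V density.
    """
    frames = list(frames)
    if not frames:
        raise EmptyInputError("accumulate_mddf requires at least one frame")
    if density_mode not in ("bulk", "total"):
        raise ValueError(f"unknown density_mode {density_mode!r}")
    half_min_box = min(float(np.min(f.box)) for f in frames) / 2.0
    if cutoff > half_min_box:
        warnings.warn(
            f"cutoff {cutoff} Å exceeds half the smallest box length "
            f"({half_min_box:.2f} Å); large-R bins sample the periodic images"
        )
    n_bins = int(np.floor(cutoff / bin_width + 0.5))
    edges = np.arange(n_bins + 1) * bin_width
    n_solute = len(frames[0].solute_xyz)

    rng = np.random.default_rng(seed)
    real_pf = np.zeros((len(frames), n_bins))
    contrib = np.zeros((n_solute, n_bins))
    ideal_raw = np.zeros(n_bins)
    far_real_pf = np.zeros(len(frames))
    far_ideal = 0.0
    total_placements = 0
    n_mol_total = 0
    volume_total = 0.0

    for fi, frame in enumerate(frames):
        ev = min_distances(frame, species)
        n_mol_total += len(ev)
        volume_total += frame.volume
        bins = np.floor(ev.distance / bin_width).astype(np.intp)
        inside = bins < n_bins
        np.add.at(real_pf[fi], bins[inside], 1.0)
        np.add.at(contrib, (ev.solute_atom_index[inside], bins[inside]), 1.0)
        far_real_pf[fi] = float(np.count_nonzero(ev.distance > d_bulk))

        iev = ideal_min_distances(frame, species, oversample=oversample, seed=rng)
        ibins = np.floor(iev.distance / bin_width).astype(np.intp)
        iinside = ibins < n_bins
        np.add.at(ideal_raw, ibins[iinside], 1.0)
        far_ideal += float(np.count_nonzero(iev.distance > d_bulk))
        total_placements += len(iev)

    n_frames = len(frames)
    volume = volume_total / n_frames
    n_mol_mean = n_mol_total / n_frames
    ideal_frac = ideal_raw / total_placements
    far_ideal_frac = far_ideal / total_placements
    rho = _bulk_density(far_real_pf.sum(), far_ideal_frac, n_frames, volume,
                        n_mol_mean, density_mode)
    if rho <= 0:
        raise InvalidDensityError(f"estimated bulk density {rho} is not positive")

    real_mean = real_pf.mean(axis=0)
    ideal_counts = rho * volume * ideal_frac
    defined = ideal_counts > 0
    mddf = np.zeros(n_bins)
    mddf[defined] = real_mean[defined] / ideal_counts[defined]

    hist = Histogram(bin_width, n_bins, real_mean, ideal_counts, n_frames, real_pf)
    return MDDFResult(
        histogram=hist,
        mddf=mddf,
        defined=defined,
        cum_real=np.cumsum(real_mean),
        cum_ideal=np.cumsum(ideal_counts),
        contributions=contrib / n_frames,
        species=species,
        bulk_density=rho,
        box_volume=volume,
        n_molecules_mean=n_mol_mean,
        ideal_frac=ideal_frac,
        far_real_per_frame=far_real_pf,
        far_ideal_frac=far_ideal_frac,
        params={
            "bin_width_A": bin_width,
            "cutoff_A": cutoff,
            "oversample": oversample,
            "seed": seed,
            "d_bulk_A": d_bulk,
            "density_mode": density_mode,
        },
    )


# ---------------------------------------------------------------------------
# Decompositions
# ---------------------------------------------------------------------------

@dataclass
class DecomposedMDDF:
    """Per-group MDDF contributions on the normalization of the total.

    ``groups[g]`` is the group's real count divided by the *total* ideal
    count, bin by bin, so the groups sum exactly to the total MDDF.
    """

    edges: np.ndarray
    species: str
    groups: dict[Hashable, np.ndarray]
    raw_counts: dict[Hashable, np.ndarray]

    def total(self) -> np.ndarray:
        return np.sum(list(self.groups.values()), axis=0)

    def to_frame(self) -> pd.DataFrame:
        data = {"r_left_A": self.edges[:-1], "r_right_A": self.edges[1:]}
        for g, arr in self.groups.items():
            data[f"group_{g}"] = arr
        return pd.DataFrame(data)

    metadata: dict = field(default_factory=dict)


def decompose(result: MDDFResult, partition: Mapping[int, Hashable]) -> DecomposedMDDF:
    """Split the MDDF into group contributions via the realizing solute atom.

    ``partition`` maps every solute atom index to a group label; an unmapped
    atom raises :class:`PartitionError`.  Contributions are normalized by the
    total ideal counts so the groups sum to the total MDDF bin-by-bin.
    """
    n_atoms = result.contributions.shape[0]
    missing = [i for i in range(n_atoms) if i not in partition]
    if missing:
        raise PartitionError(f"partition misses solute atom indices {missing[:10]}")
    labels = sorted({partition[i] for i in range(n_atoms)}, key=str)
    raw = {g: np.zeros(result.histogram.n_bins) for g in labels}
    for i in range(n_atoms):
        raw[partition[i]] += result.contributions[i]
    ideal = result.histogram.ideal_counts
    denom = np.where(result.defined, ideal, 1.0)
    groups = {g: np.where(result.defined, c / denom, 0.0) for g, c in raw.items()}
    return DecomposedMDDF(result.edges, result.species, groups, raw,
                          metadata={"result": "MDDF decomposition",
                                    "species": result.species})


def residue_partition(atoms: Sequence[AtomRecord]) -> dict[int, int]:
    """Map solute atom index → residue index (for per-residue decompositions)."""
    return {i: a.residue_index for i, a in enumerate(atoms)}


def backbone_sidechain_partition(
    atoms: Sequence[AtomRecord],
    backbone_atom_names: frozenset = DEFAULT_BACKBONE_ATOMS,
) -> dict[int, str]:
    """Map solute atom index → 'backbone' or 'sidechain' by atom name."""
    return {
        i: ("backbone" if a.name in backbone_atom_names else "sidechain")
        for i, a in enumerate(atoms)
    }


@dataclass
class DifferentialMap:
    """Signed per-group, per-bin difference of MDDF contributions (A − B)."""

    edges: np.ndarray
    diff: dict[Hashable, np.ndarray]

    def summary(self, window: tuple[float, float] | None = None) -> dict[Hashable, float]:
        """Integral of each group's difference over a distance window (Å)."""
        centers = (self.edges[:-1] + self.edges[1:]) / 2
        w = np.diff(self.edges)
        if window is None:
            sel = np.ones(len(centers), dtype=bool)
        else:
            sel = (centers >= window[0]) & (centers < window[1])
        return {g: float(np.sum(arr[sel] * w[sel])) for g, arr in self.diff.items()}

    def to_frame(self) -> pd.DataFrame:
        data = {"r_left_A": self.edges[:-1], "r_right_A": self.edges[1:]}
        for g, arr in self.diff.items():
            data[f"group_{g}"] = arr
        return pd.DataFrame(data)

    @property
    def metadata(self) -> dict:
        return {"result": "differential density map"}


def differential_density_map(a: DecomposedMDDF, b: DecomposedMDDF) -> DifferentialMap:
    """Per-group difference of contributions between two states (A − B).

    Requires identical bin grids and species; groups missing on one side are
    treated as zero contribution there.
    """
    if a.edges.shape != b.edges.shape or not np.allclose(a.edges, b.edges):
        raise IncompatibilityError("bin grids differ between the two decompositions")
    if a.species != b.species:
        raise IncompatibilityError(f"species differ: {a.species!r} vs {b.species!r}")
    keys = sorted(set(a.groups) | set(b.groups), key=str)
    zero = np.zeros(len(a.edges) - 1)
    diff = {g: a.groups.get(g, zero) - b.groups.get(g, zero) for g in keys}
    return DifferentialMap(a.edges.copy(), diff)
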