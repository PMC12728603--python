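"""Shrake–Rupley solvent-accessible surface areas and additive m-value models.

SASA is computed by sampling each atom's solvent-exposed sphere (van der
Waals radius + probe radius) with a deterministic golden-section spiral
point set and counting points not buried inside any neighbouring sphere.
Determinism (no RNG) makes areas reproducible bit-for-bit.

The additive transfer model estimates the transfer free energy of a
conformation at 1 mol/L cosolvent as

    Δμ_tr = Σ_k (A_k / A_ref,k) · Δg_k

summing over the backbone group and each side-chain type, where A_k is the
conformation's solvent-accessible area of group k, A_ref,k a reference area
and Δg_k the experimental group transfer free energy (cal/mol).  The m-value
of unfolding is the difference Δμ_tr^U − Δμ_tr^N.  Coefficient tables are
data supplied by the user (urea-type and TMAO-type parameterisations differ
only through these numbers here); the packaged table is a synthetic example
for testing, not an experimental transcription.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import SolvKBError
from .io import AtomRecord, DEFAULT_BACKBONE_ATOMS

__all__ = [
    "SASAResult",
    "CoefficientTable",
    "MValueEstimate",
    "load_radii",
    "shrake_rupley",
    "partition_sasa",
    "mvalue_additive",
]

logger = logging.getLogger("solvkb")


def load_radii(path: str | Path | None = None) -> dict[str, float]:
    """Load an element → van der Waals radius (Å) table.

    Defaults to the packaged Bondi-style set.  Format: CSV with columns
    ``element,radius_A``; '#' lines are comments.
    """
    if path is None:
        ref = importlib.resources.files("solvkb.data") / "vdw_radii.csv"
        with importlib.resources.as_file(ref) as p:
            frame = pd.read_csv(p, comment="#")
    else:
        frame = pd.read_csv(path, comment="#")
    return {str(e).strip().upper(): float(r)
            for e, r in zip(frame["element"], frame["radius_A"])}


def golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden-section spiral)."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    azimuth = np.pi * (3.0 - np.sqrt(5.0)) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(azimuth), rho * np.sin(azimuth), z])


@dataclass
class SASAResult:
    """Per-atom solvent-accessible areas with probe/radii provenance."""

    atoms: list[AtomRecord]
    atom_areas: np.ndarray        # Å²
    probe: float                  # Å
    n_points: int
    radii_table: str

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())

    @property
    def total_nm2(self) -> float:
        return self.total / 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "serial": [a.serial for a in self.atoms],
                "name": [a.name for a in self.atoms],
                "residue_name": [a.residue_name for a in self.atoms],
                "residue_index": [a.residue_index for a in self.atoms],
                "area_A2": self.atom_areas,
            }
        )

    @property
    def metadata(self) -> dict:
        return {
            "result": "SASA",
            "probe_A": f"{self.probe:g}",
            "n_sphere_points": self.n_points,
            "radii_table": self.radii_table,
            "total_A2": f"{self.total:.17g}",
            "total_nm2": f"{self.total_nm2:.17g}",
        }


def shrake_rupley(
    atoms: Sequence[AtomRecord],
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
    radii_table_id: str = "bondi-default",
) -> SASAResult:
    """Shrake–Rupley SASA with a deterministic spherical point lattice.

    Per-atom area is ``4π(r_i+probe)² × accessible/n_points``; a point is
    accessible when it lies outside every neighbouring expanded sphere.
    Neighbours are all atoms within ``r_i + r_j + 2·probe``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    atoms = list(atoms)
    if radii is None:
        radii = load_radii()
    try:
        r = np.array([radii[a.element.upper()] for a in atoms])
    except KeyError as exc:
        missing = exc.args[0]
        bad = next(a for a in atoms if a.element.upper() == missing)
        raise SolvKBError(
            f"no van der Waals radius for element {missing!r} "
            f"(atom {bad.serial} {bad.name} in {bad.residue_name}{bad.residue_index})"
        ) from exc
    xyz = np.array([[a.x, a.y, a.z] for a in atoms])
    expanded = r + probe
    sphere = golden_spiral(n_points)
    areas = np.zeros(len(atoms))
    tree = cKDTree(xyz) if len(atoms) > 1 else None
    rmax = expanded.max()
    for i in range(len(atoms)):
        pts = xyz[i] + expanded[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        if tree is not None:
            neigh = tree.query_ball_point(xyz[i], expanded[i] + rmax)
            for j in neigh:
                if j == i:
                    continue
                d = np.linalg.norm(xyz[j] - xyz[i])
                if d >= expanded[i] + expanded[j]:
                    continue
                accessible &= (np.linalg.norm(pts - xyz[j], axis=1) >= expanded[j])
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.sum() / n_points
    return SASAResult(atoms, areas, probe, n_points, radii_table_id)


def partition_sasa(
    result: SASAResult,
    backbone_atom_names: frozenset = DEFAULT_BACKBONE_ATOMS,
) -> pd.DataFrame:
    """Per-residue backbone and side-chain areas.

    Atoms whose name is in ``backbone_atom_names`` are backbone (glycine
    HA2/HA3 included in the default set); every other atom counts as side
    chain.  Backbone + side chain equals the residue total exactly.
    """
    rows: dict[tuple[int, str], dict[str, float]] = {}
    for atom, area in zip(result.atoms, result.atom_areas):
        key = (atom.residue_index, atom.residue_name)
        entry = rows.setdefault(key, {"backbone_A2": 0.0, "sidechain_A2": 0.0})
        if atom.name in backbone_atom_names:
            entry["backbone_A2"] += float(area)
        else:
            entry["sidechain_A2"] += float(area)
    frame = pd.DataFrame(
        [
            {
                "residue_index": idx,
                "residue_name": name,
                "backbone_A2": v["backbone_A2"],
                "sidechain_A2": v["sidechain_A2"],
                "total_A2": v["backbone_A2"] + v["sidechain_A2"],
            }
            for (idx, name), v in sorted(rows.items())
        ]
    )
    return frame


@dataclass
class CoefficientTable:
    """Per-group transfer free energies and reference areas (additive model).

    ``dg`` maps group name → transfer free energy (cal/mol per unit of
    A/A_ref at 1 mol/L cosolvent); ``a_ref`` maps group name → reference
    area (Å²).  The group "backbone" is mandatory; side-chain groups are
    keyed by three-letter residue name.
    """

    dg: dict[str, float]
    a_ref: dict[str, float]
    cosolvent: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if "backbone" not in self.dg:
            raise SolvKBError("coefficient table must define a 'backbone' group")
        for g, a in self.a_ref.items():
            if a <= 0:
                raise SolvKBError(f"reference area for group {g!r} must be positive")
        if set(self.dg) != set(self.a_ref):
            raise SolvKBError("dg and a_ref must cover the same groups")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoefficientTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines:
            if line.startswith("#") and "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
        frame = pd.read_csv(path, comment="#")
        dg = dict(zip(frame["group"], frame["dg_cal_per_mol"].astype(float)))
        a_ref = dict(zip(frame["group"], frame["a_ref_A2"].astype(float)))
        return cls(dg, a_ref, meta.get("cosolvent", ""), meta.get("provenance", ""))

    @classmethod
    def packaged_synthetic(cls) -> "CoefficientTable":
        """The shipped synthetic example table (testing/demonstration only)."""
        ref = importlib.resources.files("solvkb.data") / "mvalue_coeffs_synthetic.csv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_csv(p)


@dataclass
class MValueEstimate:
    """Additive-model transfer free energies and the resulting m-value."""

    dmu_N: float                  # kcal/mol at 1 mol/L
    dmu_U: float
    m_value: float                # kcal/mol/M, Δμ^U − Δμ^N
    backbone_contribution: float  # kcal/mol/M
    sidechain_contribution: float
    per_group: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return self.per_group

    @property
    def metadata(self) -> dict:
        return {
            "result": "additive m-value estimate",
            "dmu_N_kcal_mol": f"{self.dmu_N:.17g}",
            "dmu_U_kcal_mol": f"{self.dmu_U:.17g}",
            "m_value_kcal_mol_M": f"{self.m_value:.17g}",
        }


def _group_areas(result: SASAResult,
                 backbone_atom_names: frozenset) -> dict[str, float]:
    part = partition_sasa(result, backbone_atom_names)
    areas: dict[str, float] = {"backbone": float(part["backbone_A2"].sum())}
    for name, chunk in part.groupby("residue_name"):
        areas[name] = areas.get(name, 0.0) + float(chunk["sidechain_A2"].sum())
    return areas


def mvalue_additive(
    sasa_N: SASAResult,
    sasa_U: SASAResult,
    coeffs: CoefficientTable,
    backbone_atom_names: frozenset = DEFAULT_BACKBONE_ATOMS,
) -> MValueEstimate:
    """Additive-transfer-model m-value from native and denatured SASAs.

    Both conformations must share residue composition; every residue type
    present must have a side-chain group in ``coeffs`` (lookup fails loudly).
    The backbone and side-chain contributions sum to the total exactly.
    """
    comp_N = sorted({(x.residue_index, x.residue_name) for x in sasa_N.atoms})
    comp_U = sorted({(x.residue_index, x.residue_name) for x in sasa_U.atoms})
    if [c[1] for c in comp_N] != [c[1] for c in comp_U]:
        only_N = set(comp_N) - set(comp_U)
        only_U = set(comp_U) - set(comp_N)
        raise SolvKBError(
            f"residue composition mismatch between states: N-only {sorted(only_N)}, "
            f"U-only {sorted(only_U)}"
        )
    areas_N = _group_areas(sasa_N, backbone_atom_names)
    areas_U = _group_areas(sasa_U, backbone_atom_names)
    groups = sorted(set(areas_N) | set(areas_U))
    missing = [g for g in groups if g not in coeffs.dg]
    if missing:
        raise SolvKBError(f"coefficient table lacks groups {missing}")
    rows = []
    dmu_N = dmu_U = 0.0
    bb_m = sc_m = 0.0
    for g in groups:
        aN = areas_N.get(g, 0.0)
        aU = areas_U.get(g, 0.0)
        cN = (aN / coeffs.a_ref[g]) * coeffs.dg[g] / 1000.0  # cal -> kcal
        cU = (aU / coeffs.a_ref[g]) * coeffs.dg[g] / 1000.0
        dmu_N += cN
        dmu_U += cU
        if g == "backbone":
            bb_m += cU - cN
        else:
            sc_m += cU - cN
        rows.append({"group": g, "area_N_A2": aN, "area_U_A2": aU,
                     "dmu_N_kcal_mol": cN, "dmu_U_kcal_mol": cU,
                     "m_contribution_kcal_mol_M": cU - cN})
    # total defined as the sum of the two class contributions so additivity
    # holds exactly, not merely to rounding
    return MValueEstimate(dmu_N, dmu_U, bb_m + sc_m, bb_m, sc_m,
                          pd.DataFrame(rows))
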