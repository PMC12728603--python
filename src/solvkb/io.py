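"""Structure and table I/O: PDB, extended XYZ, delimited result tables.

Coordinate convention: Å everywhere, orthorhombic boxes only.  Solvent
molecules are fixed contiguous blocks of ``atoms_per_molecule`` atoms; no
connectivity is ever inferred.  All indices are 0-based internally; PDB
serial numbers are preserved only as labels.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyInputError,
    ParseError,
    UnsupportedFeatureError,
)

logger = logging.getLogger("solvkb")

#: Default backbone atom-name set (glycine HA2/HA3 count as backbone).
DEFAULT_BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "H", "HA", "HA2", "HA3", "HN", "OXT"}
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure file."""

    serial: int
    name: str
    residue_name: str
    residue_index: int
    chain: str
    x: float
    y: float
    z: float
    element: str

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class SolventSpecies:
    """A solvent component: contiguous blocks of ``atoms_per_molecule`` atoms.

    ``label`` is conventionally ``"w"`` for water and ``"c"`` for the
    cosolvent; any short string is accepted.
    """

    label: str
    atoms_per_molecule: int
    coordinates: np.ndarray  # (n_atoms, 3) Å
    molar_mass: float = 18.015  # g/mol

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if self.atoms_per_molecule < 1:
            raise ConfigurationError("atoms_per_molecule must be >= 1")
        if self.molar_mass <= 0:
            raise ConfigurationError("molar mass must be positive")
        if len(self.coordinates) % self.atoms_per_molecule != 0:
            raise ConfigurationError(
                f"species {self.label!r}: {len(self.coordinates)} atoms not divisible "
                f"by atoms_per_molecule={self.atoms_per_molecule}"
            )

    @property
    def n_molecules(self) -> int:
        return len(self.coordinates) // self.atoms_per_molecule

    def molecules(self) -> np.ndarray:
        """Coordinates reshaped to (n_molecules, atoms_per_molecule, 3)."""
        return self.coordinates.reshape(self.n_molecules, self.atoms_per_molecule, 3)


@dataclass
class SoluteMeta:
    """Solute-level metadata used by the thermodynamic layer."""

    molar_mass: float  # M_p, g/mol
    state_label: str = "N"
    backbone_atom_names: frozenset = DEFAULT_BACKBONE_ATOMS

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ConfigurationError("solute molar mass must be positive")


@dataclass
class Configuration:
    """One frame: solute coordinates, solvent species, orthorhombic box.

    ``solute`` may be given as a list of :class:`AtomRecord` (structure
    metadata retained) or directly as an ``(N, 3)`` coordinate array.
    """

    solute: Sequence[AtomRecord] | np.ndarray
    solvent_species: list[SolventSpecies]
    box: np.ndarray  # (3,) Å
    frame_id: int = 0
    meta: SoluteMeta | None = None

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ConfigurationError(f"box lengths must be positive, got {self.box}")

    @property
    def solute_xyz(self) -> np.ndarray:
        if isinstance(self.solute, np.ndarray):
            return self.solute.reshape(-1, 3)
        return np.array([[a.x, a.y, a.z] for a in self.solute], dtype=float)

    @property
    def solute_atoms(self) -> list[AtomRecord] | None:
        if isinstance(self.solute, np.ndarray):
            return None
        return list(self.solute)

    def species(self, label: str) -> SolventSpecies:
        for sp in self.solvent_species:
            if sp.label == label:
                return sp
        raise KeyError(f"no solvent species labelled {label!r} in frame {self.frame_id}")

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_PDB_FLOAT_RE = re.compile(r"^\s*-?\d+(\.\d*)?\s*$")


def _parse_pdb_atom(line: str, lineno: int) -> AtomRecord:
    # Fixed columns (1-based): serial 7-11, name 13-16, resName 18-20,
    # chain 22, resSeq 23-26, iCode 27, x 31-38, y 39-46, z 47-54, element 77-78
    if len(line) < 54:
        raise ParseError("ATOM/HETATM line shorter than coordinate columns", lineno)
    icode = line[26:27]
    if icode.strip():
        raise ParseError(f"insertion codes are not supported (found {icode!r})", lineno)
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = -1  # e.g. '*****' overflow serials; kept as label only
    name = line[12:16].strip()
    resname = line[17:20].strip()
    chain = line[21:22].strip() or " "
    try:
        resseq = int(line[22:26])
    except ValueError as exc:
        raise ParseError(f"malformed residue number {line[22:26]!r}", lineno) from exc
    coords = []
    for lo, hi, axis in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
        text = line[lo:hi]
        # PDB coordinates are fixed-decimal F8.3; scientific notation (e.g.
        # overflowed values like 1.0e99) is malformed, not a huge coordinate
        if not _PDB_FLOAT_RE.match(text):
            raise ParseError(f"malformed {axis} coordinate {text.strip()!r}", lineno)
        value = float(text)
        if not math.isfinite(value):
            raise ParseError(f"non-finite {axis} coordinate {text.strip()!r}", lineno)
        coords.append(value)
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the first alphabetic character of the atom name
        stripped = name.lstrip("0123456789")
        element = stripped[:1].upper() if stripped else ""
    return AtomRecord(serial, name, resname, resseq, chain, *coords, element)


def read_pdb_frames(path: str | Path) -> list[list[AtomRecord]]:
    """Read a PDB file; MODEL/ENDMDL blocks yield multiple frames.

    Returns a list of frames (each a list of :class:`AtomRecord` in file
    order).  Files without MODEL records yield a single frame.
    """
    frames: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    frames.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                frames.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_pdb_atom(line, lineno))
    if current:
        frames.append(current)
    frames = [f for f in frames if f]
    if not frames:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    return frames


def read_pdb(path: str | Path) -> list[AtomRecord]:
    """Read a single-structure PDB file into a list of :class:`AtomRecord`.

    Use :func:`read_pdb_frames` for multi-MODEL files.
    """
    frames = read_pdb_frames(path)
    if len(frames) > 1:
        raise ParseError(
            f"{path} contains {len(frames)} MODEL frames; use read_pdb_frames()"
        )
    return frames[0]


def write_pdb(frames: Sequence[Sequence[AtomRecord]] | Sequence[AtomRecord],
              path: str | Path) -> None:
    """Write one or more frames of atom records in fixed-column PDB format."""
    if frames and isinstance(frames[0], AtomRecord):
        frames = [frames]  # type: ignore[list-item]
    multi = len(frames) > 1
    with open(path, "w") as fh:
        for i, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL {i:>8d}\n")
            for a in frame:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.serial:>5d} {name:<4s} {a.residue_name:<3s} "
                    f"{a.chain:1s}{a.residue_index:>4d}    "
                    f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPartition:
    """Sidecar convention mapping a flat atom list onto solute + species blocks.

    The first ``n_solute_atoms`` atoms of each frame are the solute; the
    remaining atoms are consumed in order by each ``(label, n_molecules,
    atoms_per_molecule, molar_mass)`` entry.
    """

    n_solute_atoms: int
    species: list[tuple[str, int, int, float]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return self.n_solute_atoms + sum(n * apm for _, n, apm, _ in self.species)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SpeciesPartition":
        species = [
            (
                str(sp["label"]),
                int(sp["n_molecules"]),
                int(sp["atoms_per_molecule"]),
                float(sp.get("molar_mass", 18.015)),
            )
            for sp in data.get("species", [])
        ]
        return cls(n_solute_atoms=int(data["n_solute_atoms"]), species=species)


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_SOLUTE_RE = re.compile(r"Solute=(\d+)")
_SPECIES_RE = re.compile(r'Species="([^"]+)"')


def _parse_comment_partition(comment: str, lineno: int) -> SpeciesPartition | None:
    """Per-frame species partition from the comment line, when present.

    Convention: ``Solute=N Species="label:n_molecules:atoms_per_molecule:molar_mass,..."``.
    """
    sol = _SOLUTE_RE.search(comment)
    spe = _SPECIES_RE.search(comment)
    if sol is None and spe is None:
        return None
    if sol is None or spe is None:
        raise ParseError("comment must carry both Solute= and Species=", lineno)
    species = []
    for chunk in spe.group(1).split(","):
        parts = chunk.split(":")
        if len(parts) != 4:
            raise ParseError(f"malformed species entry {chunk!r}", lineno)
        species.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return SpeciesPartition(int(sol.group(1)), species)


def _parse_lattice(comment: str, lineno: int) -> np.ndarray | None:
    m = _LATTICE_RE.search(comment)
    if m is None:
        return None
    values = [float(v) for v in m.group(1).split()]
    if len(values) != 9:
        raise ParseError("Lattice must contain 9 numbers", lineno)
    mat = np.array(values, dtype=float).reshape(3, 3)
    off = mat - np.diag(np.diag(mat))
    if np.any(off != 0.0):
        raise UnsupportedFeatureError(
            f"line {lineno}: triclinic lattice is not supported (orthorhombic only)"
        )
    return np.diag(mat).copy()


def iter_xyz_frames(
    path: str | Path,
    partition: SpeciesPartition | None = None,
    box_override: Sequence[float] | None = None,
    meta: SoluteMeta | None = None,
) -> Iterator[Configuration]:
    """Lazily stream frames from an extended-XYZ trajectory.

    Each frame header is ``n_atoms`` then a comment carrying
    ``Lattice="a 0 0 0 b 0 0 0 c"``; when the Lattice key is missing a
    ``box_override`` must be supplied.  Atom-to-species assignment comes
    from a ``Solute=``/``Species=`` partition in the comment line when
    present (this package writes one, which also supports frame-to-frame
    molecule-count fluctuations), falling back to the sidecar ``partition``.
    """
    box_override_arr = None if box_override is None else np.asarray(box_override, float)
    with open(path) as fh:
        lineno = 0
        frame_id = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                break
            if not header.strip():
                continue
            try:
                n_atoms = int(header)
            except ValueError as exc:
                raise ParseError(f"expected atom count, got {header.strip()!r}", lineno) from exc
            comment = fh.readline()
            lineno += 1
            box = _parse_lattice(comment, lineno)
            if box is None:
                if box_override_arr is None:
                    raise ConfigurationError(
                        f"frame {frame_id}: no Lattice in comment and no box override"
                    )
                box = box_override_arr
            coords = np.empty((n_atoms, 3), dtype=float)
            for i in range(n_atoms):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                if len(parts) < 4:
                    raise ParseError(
                        f"frame {frame_id} declares {n_atoms} atoms but ended early",
                        lineno,
                    )
                try:
                    coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                except ValueError as exc:
                    raise ParseError(f"malformed coordinates {parts[1:4]}", lineno) from exc
            frame_partition = _parse_comment_partition(comment, lineno) or partition
            if frame_partition is None:
                raise ConfigurationError(
                    f"frame {frame_id}: no species partition in comment and no "
                    "sidecar partition supplied"
                )
            if n_atoms != frame_partition.n_atoms:
                raise ParseError(
                    f"frame {frame_id}: {n_atoms} atoms but partition expects "
                    f"{frame_partition.n_atoms}",
                    lineno,
                )
            solute = coords[: frame_partition.n_solute_atoms]
            species = []
            offset = frame_partition.n_solute_atoms
            for label, n_mol, apm, mass in frame_partition.species:
                count = n_mol * apm
                species.append(
                    SolventSpecies(label, apm, coords[offset : offset + count], mass)
                )
                offset += count
            yield Configuration(solute, species, box, frame_id=frame_id, meta=meta)
            frame_id += 1


def read_xyz_frames(
    path: str | Path,
    partition: SpeciesPartition | None = None,
    box_override: Sequence[float] | None = None,
    meta: SoluteMeta | None = None,
) -> list[Configuration]:
    """Eager version of :func:`iter_xyz_frames`; errors on an empty file."""
    frames = list(iter_xyz_frames(path, partition, box_override, meta))
    if not frames:
        raise EmptyInputError(f"{path}: no frames")
    return frames


def write_xyz_frames(frames: Iterable[Configuration], path: str | Path,
                     element: str = "X") -> None:
    """Write frames as extended XYZ (solute atoms first, then species blocks)."""
    with open(path, "w") as fh:
        for frame in frames:
            solute = frame.solute_xyz
            blocks = [solute] + [sp.coordinates for sp in frame.solvent_species]
            coords = np.vstack(blocks) if blocks else np.empty((0, 3))
            a, b, c = frame.box
            species_desc = ",".join(
                f"{sp.label}:{sp.n_molecules}:{sp.atoms_per_molecule}:{sp.molar_mass:g}"
                for sp in frame.solvent_species
            )
            fh.write(f"{len(coords)}\n")
            fh.write(
                f'Lattice="{a:.10g} 0 0 0 {b:.10g} 0 0 0 {c:.10g}" '
                f'Solute={len(solute)} Species="{species_desc}" '
                f"frame={frame.frame_id}\n"
            )
            atoms = frame.solute_atoms
            names = [r.element or element for r in atoms] if atoms else []
            names += [element] * (len(coords) - len(names))
            for nm, (x, y, z) in zip(names, coords):
                fh.write(f"{nm} {x:.10f} {y:.10f} {z:.10f}\n")


# ---------------------------------------------------------------------------
# Delimited result tables
# ---------------------------------------------------------------------------

def write_table(result, path: str | Path) -> None:
    """Write any result exposing ``to_frame()``/``metadata`` as delimited text.

    Output: '#'-prefixed ``key = value`` header lines, then CSV with a header
    row naming columns (units included in the column names).  Floats carry 17
    significant digits so a round-trip read reproduces them exactly.
    """
    if hasattr(result, "to_frame"):
        frame: pd.DataFrame = result.to_frame()
        metadata: Mapping = getattr(result, "metadata", {}) or {}
    elif isinstance(result, pd.DataFrame):
        frame, metadata = result, {}
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}: no to_frame()")
    if frame.empty:
        warnings.warn(f"writing header-only table to {path} (empty result)")
    with open(path, "w") as fh:
        for key, value in metadata.items():
            fh.write(f"# {key} = {value}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a table written by :func:`write_table`; returns (frame, metadata)."""
    metadata: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        frame = pd.read_csv(fh)
    return frame, metadata
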