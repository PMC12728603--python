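"""End-to-end, file-mediated runs with a machine-readable manifest.

``run_solvation`` takes a trajectory to Γ (frames → MDDF per species → KBI →
Γ); ``run_transfer`` takes Γ series of two or more conformational states to
transfer free energies and their pairwise differences.  Every run writes a
JSON manifest recording inputs, parameters, the seed and a SHA-256 hash of
each output file, so a rerun with the same seed reproduces every hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError
from .io import SpeciesPartition, read_table, read_xyz_frames, write_table
from .kbi import (
    ActivityModel,
    GammaSeries,
    TransferCurve,
    delta_transfer,
    gamma,
    kbi_profile,
    transfer_free_energy,
)
from .mddf import accumulate_mddf

logger = logging.getLogger("solvkb")

__all__ = ["RunConfig", "run_solvation", "run_transfer"]


@dataclass
class RunConfig:
    """Validated configuration of a solvation run."""

    frames: str
    output_dir: str
    partition: str | None = None
    bin_width: float = 0.05
    cutoff: float = 20.0
    oversample: int = 10
    seed: int = 0
    d_bulk: float = 10.0
    plateau_window: float = 5.0
    cosolvent_label: str = "c"
    water_label: str = "w"
    box_override: tuple[float, float, float] | None = None
    temperature: float = 298.15
    transfer_enabled: bool = False
    ideal_activity: bool = True
    activity_table: str | None = None
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        if "box_override" in kwargs and kwargs["box_override"] is not None:
            kwargs["box_override"] = tuple(kwargs["box_override"])
        return cls(**kwargs, extra=extra)

    def validate(self) -> None:
        if not Path(self.frames).exists():
            raise ConfigurationError(f"frames file not found: {self.frames}")
        if self.partition is not None and not Path(self.partition).exists():
            raise ConfigurationError(f"partition file not found: {self.partition}")
        if self.transfer_enabled and not self.ideal_activity:
            if not self.activity_table:
                raise ConfigurationError(
                    "transfer stage enabled with non-ideal activity but no "
                    "activity_table given"
                )
            if not Path(self.activity_table).exists():
                raise ConfigurationError(
                    f"activity table not found: {self.activity_table}"
                )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, inputs: dict, params: dict,
                    outputs: list[Path], ok: bool = True) -> Path:
    manifest = {
        "software": {"name": "solvkb", "version": __version__},
        "inputs": inputs,
        "parameters": params,
        "complete": ok,
        "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_solvation(config: RunConfig) -> dict[str, Path]:
    """Frames → MDDF (both species) → KBI → Γ, all written as tables.

    Returns a mapping of logical output names to paths; a manifest with
    content hashes is always written last.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    partition = None
    if config.partition is not None:
        with open(config.partition) as fh:
            partition = SpeciesPartition.from_mapping(yaml.safe_load(fh))
    t0 = time.perf_counter()
    frames = read_xyz_frames(config.frames, partition, config.box_override)
    logger.info("read %d frames in %.2f s", len(frames), time.perf_counter() - t0)

    outputs: dict[str, Path] = {}
    profiles = {}
    for i, label in enumerate((config.water_label, config.cosolvent_label)):
        t0 = time.perf_counter()
        result = accumulate_mddf(
            frames, label, bin_width=config.bin_width, cutoff=config.cutoff,
            oversample=config.oversample, seed=config.seed + i,
            d_bulk=config.d_bulk,
        )
        logger.info("MDDF[%s] in %.2f s (rho=%.3g /A^3)", label,
                    time.perf_counter() - t0, result.bulk_density)
        profile = kbi_profile(result, plateau_window=config.plateau_window)
        mddf_path = outdir / f"mddf_{label}.csv"
        kbi_path = outdir / f"kbi_{label}.csv"
        write_table(result, mddf_path)
        write_table(profile, kbi_path)
        outputs[f"mddf_{label}"] = mddf_path
        outputs[f"kbi_{label}"] = kbi_path
        profiles[label] = profile

    g = gamma(profiles[config.cosolvent_label], profiles[config.water_label])
    series = GammaSeries("run", [g])
    gamma_path = outdir / "gamma.csv"
    write_table(series, gamma_path)
    outputs["gamma"] = gamma_path

    params = {k: getattr(config, k) for k in (
        "bin_width", "cutoff", "oversample", "seed", "d_bulk",
        "plateau_window", "cosolvent_label", "water_label", "temperature")}
    outputs["manifest"] = _write_manifest(
        outdir,
        {"frames": str(config.frames),
         "partition": str(config.partition) if config.partition else "comment-embedded"},
        params,
        list(outputs.values()),
    )
    return outputs


def run_transfer(
    gamma_tables: dict[str, str | Path],
    output_dir: str | Path,
    temperature: float,
    M_p: float,
    M_c: float,
    activity_table: str | Path | None = None,
    reference_state: str | None = None,
    n_nodes: int = 1000,
) -> dict[str, Path]:
    """Γ series of ≥ 2 states → per-state transfer curves and δΔμ^U−N tables.

    ``gamma_tables`` maps state label → Γ-series table; states must share the
    concentration grid.  ``reference_state`` defaults to ``"N"`` when present,
    else the first state; every other state is differenced against it.
    """
    if len(gamma_tables) < 2:
        raise ConfigurationError("transfer differences need at least two states")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    activity = (ActivityModel.from_table(activity_table)
                if activity_table else ActivityModel.ideal())

    series: dict[str, GammaSeries] = {}
    for state, path in gamma_tables.items():
        frame, _ = read_table(path)
        series[state] = GammaSeries.from_frame(frame, state)
    grids = {state: tuple(s.concentrations) for state, s in series.items()}
    if len(set(grids.values())) != 1:
        raise ConfigurationError(f"states on different concentration grids: {grids}")

    if reference_state is None:
        reference_state = "N" if "N" in series else next(iter(series))
    curves: dict[str, TransferCurve] = {}
    outputs: dict[str, Path] = {}
    for state, s in series.items():
        curve = transfer_free_energy(s, activity, temperature, M_p, M_c,
                                     n_nodes=n_nodes)
        curves[state] = curve
        path = outdir / f"transfer_{state}.csv"
        write_table(curve, path)
        outputs[f"transfer_{state}"] = path
    for state, curve in curves.items():
        if state == reference_state:
            continue
        delta = delta_transfer(curve, curves[reference_state])
        path = outdir / f"delta_transfer_{state}_minus_{reference_state}.csv"
        write_table(delta, path)
        outputs[f"delta_{state}"] = path

    outputs["manifest"] = _write_manifest(
        outdir,
        {state: str(p) for state, p in gamma_tables.items()},
        {"temperature": temperature, "M_p": M_p, "M_c": M_c,
         "n_nodes": n_nodes, "reference_state": reference_state,
         "activity": str(activity_table) if activity_table else "ideal"},
        list(outputs.values()),
    )
    return outputs
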