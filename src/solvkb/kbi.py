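"""Kirkwood–Buff integrals, preferential interactions and transfer free energies.

From the cumulative minimum-distance counts of an :class:`~solvkb.mddf.MDDFResult`
the finite-volume Kirkwood–Buff integral is

    G_ps(R) = (1/ρ_s) · [N_ps(R) − N_ps*(R)]

the excess volume occupied by species s around the solute p relative to an
ideal distribution at the bulk density ρ_s.  In the infinitely dilute solute
limit the preferential interaction parameter follows as

    Γ_pc ≈ ρ_c · [G_pc(R) − G_pw(R)]

with R large enough to contain the solvation perturbation.  Γ > 0 means the
cosolvent accumulates at the solute (urea-like); Γ < 0 means preferential
hydration (TMAO-like).  The Wyman linkage relation ties the difference of Γ
between two conformational states to the shift of their equilibrium with
cosolvent activity, and integrating

    (∂μ_p/∂m_c) = −Γ_pc · (R T M_p / M_c) · (1/m_c + ∂ln γ_c/∂m_c)

from pure water to concentration m_c gives the transfer free energy of a
fixed conformation (Lin–Timasheff protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import IncompatibilityError, InvalidDensityError
from .mddf import MDDFResult
from .units import A3_PER_MOLECULE_TO_L_PER_MOL, R_GAS_KCAL

__all__ = [
    "KBIProfile",
    "Gamma",
    "GammaSeries",
    "ActivityModel",
    "TransferCurve",
    "kbi_profile",
    "gamma",
    "wyman_delta",
    "transfer_free_energy",
    "delta_transfer",
]


@dataclass
class KBIProfile:
    """Distance-resolved Kirkwood–Buff integral G_ps(R)."""

    R: np.ndarray                 # right bin edges, Å
    G: np.ndarray                 # Å³/molecule
    species: str
    rho: float                    # molecules/Å³
    plateau: float                # mean G over the last plateau_window Å
    plateau_window: tuple[float, float]
    plateau_se: float
    flatness: float               # max-min of G over the plateau window
    blocks: np.ndarray = field(repr=False, default=None)  # (n_blocks, len(R))

    @property
    def G_L_per_mol(self) -> np.ndarray:
        return self.G * A3_PER_MOLECULE_TO_L_PER_MOL

    @property
    def plateau_L_per_mol(self) -> float:
        return self.plateau * A3_PER_MOLECULE_TO_L_PER_MOL

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"R_A": self.R, "G_A3": self.G, "G_L_per_mol": self.G_L_per_mol}
        )

    @classmethod
    def from_table(cls, frame: pd.DataFrame, metadata: dict) -> "KBIProfile":
        """Rebuild a profile written by :func:`solvkb.io.write_table`.

        Block data are not serialised; the plateau standard error is restored
        from the metadata.
        """
        lo, _, hi = metadata["plateau_window_A"].partition("..")
        return cls(
            R=frame["R_A"].to_numpy(),
            G=frame["G_A3"].to_numpy(),
            species=metadata.get("species", ""),
            rho=float(metadata["rho_per_A3"]),
            plateau=float(metadata["plateau_A3"]),
            plateau_window=(float(lo), float(hi)),
            plateau_se=float(metadata["plateau_se_A3"]),
            flatness=float(metadata["flatness_A3"]),
        )

    @property
    def metadata(self) -> dict:
        return {
            "result": "KBI profile",
            "species": self.species,
            "rho_per_A3": f"{self.rho:.17g}",
            "plateau_A3": f"{self.plateau:.17g}",
            "plateau_L_per_mol": f"{self.plateau_L_per_mol:.17g}",
            "plateau_window_A": f"{self.plateau_window[0]:g}..{self.plateau_window[1]:g}",
            "plateau_se_A3": f"{self.plateau_se:.17g}",
            "flatness_A3": f"{self.flatness:.17g}",
        }


def kbi_profile(result: MDDFResult, plateau_window: float = 5.0,
                n_blocks: int = 5) -> KBIProfile:
    """Distance-resolved KBI from an MDDF result.

    The plateau is the mean of G(R) over the final ``plateau_window`` Å of
    the grid; its standard error comes from block averaging the frames
    (``n_blocks`` contiguous blocks) and a flatness diagnostic (max − min over
    the window) is reported alongside.
    """
    rho = result.bulk_density
    if rho <= 0:
        raise InvalidDensityError(f"bulk density must be positive, got {rho}")
    R = result.edges[1:]
    G = result.cum_real / rho - result.box_volume * np.cumsum(result.ideal_frac)

    window = (max(R[-1] - plateau_window, R[0]), R[-1])
    sel = R >= window[0]
    plateau = float(G[sel].mean())
    flatness = float(G[sel].max() - G[sel].min())

    blocks = None
    plateau_se = float("nan")
    rpf = result.histogram.real_per_frame
    if rpf is not None and len(rpf) >= n_blocks:
        splits = np.array_split(np.arange(len(rpf)), n_blocks)
        blocks = np.empty((n_blocks, len(R)))
        for bi, idx in enumerate(splits):
            cum = np.cumsum(rpf[idx].mean(axis=0))
            # per-block bulk density so the block spread carries the density
            # uncertainty, which dominates G at large R
            far_b = result.far_real_per_frame[idx].mean()
            if result.far_ideal_frac > 0 and far_b > 0:
                rho_b = far_b / (result.far_ideal_frac * result.box_volume)
            else:
                rho_b = rho
            blocks[bi] = cum / rho_b - result.box_volume * np.cumsum(result.ideal_frac)
        bp = blocks[:, sel].mean(axis=1)
        plateau_se = float(bp.std(ddof=1) / np.sqrt(n_blocks))
    return KBIProfile(R, G, result.species, rho, plateau, window, plateau_se,
                      flatness, blocks)


def kbi_profile_from_table(frame: pd.DataFrame, metadata: dict,
                           plateau_window: float = 5.0) -> KBIProfile:
    """Rebuild a KBI profile from a written MDDF table (file-mediated stages).

    Block-averaged uncertainties are not recoverable from the table; the
    plateau standard error is reported as NaN.
    """
    rho = float(metadata["bulk_density_per_A3"])
    if rho <= 0:
        raise InvalidDensityError(f"bulk density must be positive, got {rho}")
    R = frame["r_right_A"].to_numpy()
    G = (frame["cum_real_N"].to_numpy() - frame["cum_ideal_Nstar"].to_numpy()) / rho
    window = (max(R[-1] - plateau_window, R[0]), R[-1])
    sel = R >= window[0]
    plateau = float(G[sel].mean())
    flatness = float(G[sel].max() - G[sel].min())
    species = metadata.get("species", "")
    return KBIProfile(R, G, species, rho, plateau, window, float("nan"), flatness)


@dataclass
class Gamma:
    """Preferential interaction parameter Γ_pc (molecules) with uncertainty."""

    value: float
    error: float
    R: float
    rho_c: float
    state: str = ""
    concentration: float = float("nan")  # m_c, mol/L (or mol/kg, as configured)

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("uncertainty must be non-negative")


def gamma(pc: KBIProfile, pw: KBIProfile, R: float | None = None,
          state: str = "", concentration: float = float("nan")) -> Gamma:
    """Γ_pc = ρ_c·[G_pc(R) − G_pw(R)] with block-averaged uncertainty.

    ``R`` defaults to the upper edge of the plateau window, in which case the
    plateau means are differenced; an explicit R uses the profile values at
    the nearest grid point.  Both profiles must share the R grid.
    """
    if pc.R.shape != pw.R.shape or not np.allclose(pc.R, pw.R):
        raise IncompatibilityError("KBI profiles are on different R grids")
    rho_c = pc.rho
    if R is None:
        value = rho_c * (pc.plateau - pw.plateau)
        if pc.blocks is not None and pw.blocks is not None:
            sel = pc.R >= pc.plateau_window[0]
            gb = rho_c * (pc.blocks[:, sel].mean(axis=1) - pw.blocks[:, sel].mean(axis=1))
            err = float(gb.std(ddof=1) / np.sqrt(len(gb)))
        else:
            err = rho_c * float(np.hypot(pc.plateau_se, pw.plateau_se))
        return Gamma(float(value), err, float(pc.R[-1]), rho_c, state, concentration)
    i = int(np.argmin(np.abs(pc.R - R)))
    value = rho_c * (pc.G[i] - pw.G[i])
    if pc.blocks is not None and pw.blocks is not None:
        gb = rho_c * (pc.blocks[:, i] - pw.blocks[:, i])
        err = float(gb.std(ddof=1) / np.sqrt(len(gb)))
    else:
        err = 0.0
    return Gamma(float(value), err, float(pc.R[i]), rho_c, state, concentration)


@dataclass
class GammaSeries:
    """Γ_pc for one conformational state across cosolvent concentrations."""

    state: str
    gammas: list[Gamma]

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([g.concentration for g in self.gammas])

    @property
    def values(self) -> np.ndarray:
        return np.array([g.value for g in self.gammas])

    @property
    def errors(self) -> np.ndarray:
        return np.array([g.error for g in self.gammas])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "m_c": self.concentrations,
                "gamma": self.values,
                "gamma_se": self.errors,
                "R_A": [g.R for g in self.gammas],
                "rho_c_per_A3": [g.rho_c for g in self.gammas],
            }
        )

    @property
    def metadata(self) -> dict:
        return {"result": "Gamma series", "state": self.state}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, state: str) -> "GammaSeries":
        gammas = [
            Gamma(row.gamma, row.gamma_se, row.R_A, row.rho_c_per_A3, state, row.m_c)
            for row in frame.itertuples()
        ]
        return cls(state, gammas)


@dataclass
class DeltaGamma:
    """Wyman-linkage ΔΓ = Γ^U − Γ^N with quadrature-propagated error."""

    value: float
    error: float
    interpretation: str


def wyman_delta(gamma_U: Gamma, gamma_N: Gamma) -> DeltaGamma:
    """ΔΓ_pc = Γ^U − Γ^N; its sign gives the direction of the linkage shift.

    ΔΓ > 0 means increasing cosolvent concentration favors the denatured
    state (∂ln K/∂ln a_c > 0); ΔΓ < 0 favors the native state.
    """
    value = gamma_U.value - gamma_N.value
    error = float(np.hypot(gamma_U.error, gamma_N.error))
    if value > 0:
        interp = "positive: cosolvent favors the denatured (U) state"
    elif value < 0:
        interp = "negative: cosolvent favors the native (N) state"
    else:
        interp = "zero: no linkage shift"
    return DeltaGamma(float(value), error, interp)


# ---------------------------------------------------------------------------
# Activities and transfer free energies
# ---------------------------------------------------------------------------

class ActivityModel:
    """Cosolvent activity coefficient γ_c(m_c) from a tabulated curve.

    Stores (m_c, ln γ_c) pairs with ∂ln γ_c/∂m_c by central differences;
    :meth:`ideal` gives γ_c ≡ 1.  Concentration units (mol/kg or mol/L) are
    whatever the table uses — they only need to match the Γ series.
    """

    def __init__(self, m: np.ndarray | None = None,
                 ln_gamma: np.ndarray | None = None):
        if m is None:
            self.m = None
            self.ln_gamma = None
            self.dlng_dm_nodes = None
            self.is_ideal = True
            return
        m = np.asarray(m, dtype=float)
        ln_gamma = np.asarray(ln_gamma, dtype=float)
        if m.ndim != 1 or m.shape != ln_gamma.shape:
            raise ValueError("m and ln_gamma must be equal-length 1-D arrays")
        if np.any(np.diff(m) <= 0):
            raise ValueError("m_c must be strictly increasing")
        deriv = np.gradient(ln_gamma, m)
        if not np.all(np.isfinite(deriv)):
            raise ValueError("activity derivative is not finite")
        self.m = m
        self.ln_gamma = ln_gamma
        self.dlng_dm_nodes = deriv
        self.is_ideal = False

    @classmethod
    def ideal(cls) -> "ActivityModel":
        return cls()

    @classmethod
    def from_table(cls, path) -> "ActivityModel":
        """Two-column delimited text (m_c, ln γ_c); '#' lines are comments."""
        data = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
        return cls(data[:, 0], data[:, 1])

    def dlng_dm(self, m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        if self.is_ideal:
            return np.zeros_like(m)
        return np.interp(m, self.m, self.dlng_dm_nodes)


@dataclass
class TransferCurve:
    """Transfer free energy Δμ_p,tr(m_c) of one fixed conformation."""

    state: str
    m: np.ndarray                 # concentration grid (starts at 0)
    dmu: np.ndarray               # kcal/mol, Δμ_p,tr(0) = 0
    integrand: np.ndarray         # ∂μ_p/∂m_c at the grid nodes, kcal/mol per unit m
    temperature: float            # K

    def at(self, m: float) -> float:
        return float(np.interp(m, self.m, self.dmu))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"m_c": self.m, "dmu_tr_kcal_mol": self.dmu,
             "integrand_kcal_mol_per_m": self.integrand}
        )

    @property
    def metadata(self) -> dict:
        return {"result": "transfer free energy", "state": self.state,
                "temperature_K": f"{self.temperature:g}"}


def transfer_free_energy(
    series: GammaSeries,
    activity: ActivityModel,
    T: float,
    M_p: float,
    M_c: float,
    n_nodes: int = 1000,
    include_mass_ratio: bool = True,
) -> TransferCurve:
    """Numerically integrate the chemical-potential derivative to Δμ_p,tr(m).

    Γ(m) is interpolated piecewise-linearly through the series with the
    physically forced anchor Γ(0) = 0 (Γ = ρ_c[G_pc − G_pw] vanishes with
    ρ_c), which also removes the 1/m_c singularity of the integrand: at m = 0
    the integrand limit is −R·T·(M_p/M_c) times the initial slope of Γ,
    estimated to quadratic accuracy from the first two series nodes.
    Integration is trapezoidal on a grid of ``n_nodes`` plus the series
    nodes.  ``include_mass_ratio=False`` drops the M_p/M_c factor (molal
    convention variant).
    """
    m_series = series.concentrations
    if len(m_series) < 2:
        raise ValueError("need Γ at >= 2 concentrations")
    if np.any(m_series <= 0):
        raise ValueError("series concentrations must be positive (Γ(0)=0 is implicit)")
    if np.any(np.diff(m_series) <= 0):
        raise ValueError("series concentrations must be strictly increasing")
    m_anchor = np.concatenate(([0.0], m_series))
    g_anchor = np.concatenate(([0.0], series.values))

    m_max = m_series[-1]
    grid = np.unique(np.concatenate([np.linspace(0.0, m_max, n_nodes), m_series]))
    gamma_m = np.interp(grid, m_anchor, g_anchor)

    prefac = R_GAS_KCAL * T * (M_p / M_c if include_mass_ratio else 1.0)
    # dΓ/dm at m=0 from the parabola through (0,0) and the first two nodes
    m1, m2 = m_series[0], m_series[1]
    g1, g2 = series.values[0], series.values[1]
    slope0 = (g1 * m2**2 - g2 * m1**2) / (m1 * m2 * (m2 - m1))
    integrand = np.empty_like(grid)
    pos = grid > 0
    integrand[pos] = -gamma_m[pos] * prefac * (1.0 / grid[pos]
                                               + activity.dlng_dm(grid[pos]))
    integrand[~pos] = -prefac * slope0
    dmu = np.concatenate(([0.0], cumulative_trapezoid(integrand, grid)))
    return TransferCurve(series.state, grid, dmu, integrand, T)


@dataclass
class DeltaTransferCurve:
    """δΔμ_p,tr^U−N(m_c): cosolvent effect on the N ⇌ U folding free energy."""

    state_U: str
    state_N: str
    m: np.ndarray
    delta_dmu: np.ndarray         # kcal/mol; negative = cosolvent favors unfolding
    temperature: float

    def at(self, m: float) -> float:
        return float(np.interp(m, self.m, self.delta_dmu))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"m_c": self.m, "delta_dmu_U_minus_N_kcal_mol": self.delta_dmu})

    @property
    def metadata(self) -> dict:
        return {"result": "delta transfer free energy",
                "state_U": self.state_U, "state_N": self.state_N,
                "temperature_K": f"{self.temperature:g}"}


def delta_transfer(curve_U: TransferCurve, curve_N: TransferCurve) -> DeltaTransferCurve:
    """Pointwise δΔμ = Δμ_U − Δμ_N on a shared grid and temperature."""
    if curve_U.temperature != curve_N.temperature:
        raise IncompatibilityError("transfer curves at different temperatures")
    if curve_U.m.shape != curve_N.m.shape or not np.allclose(curve_U.m, curve_N.m):
        raise IncompatibilityError("transfer curves on different concentration grids")
    return DeltaTransferCurve(
        curve_U.state, curve_N.state, curve_U.m.copy(),
        curve_U.dmu - curve_N.dmu, curve_U.temperature,
    )
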