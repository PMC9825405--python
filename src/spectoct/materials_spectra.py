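"""Energy-dependent mass attenuation of chemical species near an absorption edge.

XANES (X-ray absorption near-edge structure) contrast rests on the fact that
the mass attenuation coefficient µ/ρ of an element rises abruptly at its
K edge and carries a "white line" peak just above it whose position shifts
with oxidation state.  Here the near-edge structure is parameterised with a
standard phenomenological form

    µ/ρ(E) = pre-edge line  +  jump · (1/2 + arctan((E − E0)/w) / π)
                            +  A · exp(−(E − Ewl)² / (2 σ²)),

an arctan edge step of half-width ``w`` plus a Gaussian white line — smooth,
differentiable, and adequate for selecting acquisition energies and driving
the forward simulator.  Ab-initio XANES theory and EXAFS oscillations are out
of scope.

Tabulated off-edge µ/ρ anchor values (elemental Se, PMMA, boron nitride,
cellulose) ship as a small CSV (``data/attenuation_anchors.csv``) holding
standard-table values rounded to two significant figures; between anchors the
smooth matrix spectra are scaled with the photoelectric ``E^-3`` law.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "EnergyGrid",
    "EdgeParams",
    "SpeciesSpectrum",
    "edge_spectrum_model",
    "normalize_xanes",
    "validate_acquisition_energies",
    "mass_for_target_mux",
    "load_attenuation_anchors",
    "anchor_mu_rho",
    "default_energy_grid",
    "default_acquisition_energies",
    "default_se_species",
    "matrix_spectrum",
    "read_spectra_csv",
    "write_spectra_csv",
    "SE_EDGE_PARAMS",
]

#: Acquisition photon energies A–D (keV) bracketing the Se K white lines.
ACQUISITION_ENERGIES_KEV = (12.645, 12.658, 12.662, 12.685)


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly increasing photon energies in keV."""

    energies: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "energies", e)
        if e.ndim != 1 or e.size == 0:
            raise ValueError("energies must be a non-empty 1-D array")
        if np.any(e <= 0):
            raise ValueError("all energies must be > 0 keV")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")

    def __len__(self) -> int:
        return int(self.energies.size)


@dataclass(frozen=True)
class EdgeParams:
    """Parameters of the arctan-step + Gaussian white-line edge model.

    Energies in keV, widths in eV, amplitudes in cm²/g on whatever basis the
    spectrum uses (pure element or compound).
    """

    pre_edge_level: float  # cm²/g at E0
    pre_edge_slope: float  # cm²/g per keV
    edge_energy: float  # E0, keV
    edge_jump: float  # cm²/g
    edge_width: float  # arctan half-width, eV
    white_line_amplitude: float  # cm²/g
    white_line_center: float  # keV
    white_line_width: float  # Gaussian sigma, eV

    def __post_init__(self) -> None:
        if self.edge_jump < 0 or self.edge_width <= 0 or self.white_line_width <= 0:
            raise ValueError("edge_jump must be >= 0 and widths > 0")
        if self.white_line_amplitude < 0:
            raise ValueError("white_line_amplitude must be >= 0")
        if self.white_line_center < self.edge_energy:
            raise ValueError(
                f"white_line_center {self.white_line_center} keV lies below "
                f"edge_energy {self.edge_energy} keV"
            )


@dataclass(frozen=True)
class SpeciesSpectrum:
    """Mass attenuation µ/ρ of one species sampled on an energy grid.

    ``mu_rho`` is in cm²/g (or arbitrary units after normalisation, flagged
    by ``normalized``); linear interpolation between grid points.
    """

    species_name: str
    grid: EnergyGrid
    mu_rho: np.ndarray
    edge_params: EdgeParams | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_rho, dtype=float)
        object.__setattr__(self, "mu_rho", mu)
        if mu.shape != self.grid.energies.shape:
            raise ValueError("mu_rho and grid shapes differ")
        if not self.normalized and np.any(mu < 0):
            raise ValueError(f"negative mu_rho in spectrum {self.species_name!r}")

    def __call__(self, energy_kev: float | np.ndarray) -> float | np.ndarray:
        """Interpolated µ/ρ at ``energy_kev``; energies outside the grid raise."""
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.grid.energies[0], self.grid.energies[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy {energy_kev} keV outside spectrum grid [{lo}, {hi}] "
                f"of {self.species_name!r}"
            )
        out = np.interp(e, self.grid.energies, self.mu_rho)
        return float(out) if out.ndim == 0 else out


def edge_spectrum_model(grid: EnergyGrid, params: EdgeParams, name: str = "species") -> SpeciesSpectrum:
    """Evaluate the arctan-step + Gaussian white-line model on ``grid``.

    Raises ``ValueError`` if the parameter combination produces a negative
    µ/ρ anywhere on the grid.
    """
    e = grid.energies
    w_kev = params.edge_width * 1e-3
    sigma_kev = params.white_line_width * 1e-3
    line = params.pre_edge_level + params.pre_edge_slope * (e - params.edge_energy)
    step = params.edge_jump * (0.5 + np.arctan((e - params.edge_energy) / w_kev) / np.pi)
    wl = params.white_line_amplitude * np.exp(
        -0.5 * ((e - params.white_line_center) / sigma_kev) ** 2
    )
    mu = line + step + wl
    if np.any(mu < 0):
        raise ValueError(
            f"edge parameters for {name!r} give negative mu_rho "
            f"(min {mu.min():.3g} cm^2/g)"
        )
    return SpeciesSpectrum(name, grid, mu, edge_params=params)


def normalize_xanes(
    spectrum: SpeciesSpectrum, plot_range: tuple[float, float]
) -> SpeciesSpectrum:
    """Pre-edge background subtraction + equal-area normalisation.

    A straight line is fitted to the spectrum below the edge (below
    ``E0 − 3·edge_width``; all points below the range midpoint if no edge
    parameters are attached) and subtracted; the result is scaled so its
    trapezoidal integral over ``plot_range`` equals 1.  Spectra differing
    only by an overall scale therefore normalise identically.
    """
    e = spectrum.grid.energies
    lo, hi = plot_range
    if lo >= hi or lo < e[0] or hi > e[-1]:
        raise ValueError(f"plot_range {plot_range} not within grid [{e[0]}, {e[-1]}]")
    if spectrum.edge_params is not None:
        cut = spectrum.edge_params.edge_energy - 3e-3 * spectrum.edge_params.edge_width
    else:
        cut = 0.5 * (lo + hi)
    pre = e < cut
    if pre.sum() < 2:
        raise ValueError("no pre-edge region on the grid to fit a background line")
    coef = np.polyfit(e[pre], spectrum.mu_rho[pre], 1)
    sub = spectrum.mu_rho - np.polyval(coef, e)
    sel = (e >= lo) & (e <= hi)
    area = np.trapezoid(sub[sel], e[sel])
    if area <= 0 or not np.isfinite(area):
        raise ValueError(
            f"background-subtracted spectrum {spectrum.species_name!r} has "
            f"non-positive area {area:.3g} over the plot range; cannot normalise"
        )
    return replace(spectrum, mu_rho=sub / area, normalized=True)


def validate_acquisition_energies(
    energies: EnergyGrid, spectra: list[SpeciesSpectrum]
) -> dict[str, bool]:
    """Check the four acquisition energies against the species white lines.

    ``energies`` must hold exactly four values A < B < C < D and ``spectra``
    the three species ordered by rising white-line energy (Se(0), Se(IV),
    Se(VI) in the selenium case).  The constraints (all strict):

    * A below every edge energy,
    * WL(species 1) < B < WL(species 2),
    * WL(species 2) < C < WL(species 3),
    * D above every white line.

    Returns a pass/fail report; violations never raise.
    """
    if len(energies) != 4:
        raise ValueError(f"need exactly 4 acquisition energies, got {len(energies)}")
    if len(spectra) != 3:
        raise ValueError(f"need exactly 3 species spectra, got {len(spectra)}")
    for s in spectra:
        if s.edge_params is None:
            raise ValueError(f"spectrum {s.species_name!r} carries no edge parameters")
    a, b, c, d = energies.energies
    e0 = [s.edge_params.edge_energy for s in spectra]
    wl = [s.edge_params.white_line_center for s in spectra]
    return {
        "A_below_all_edges": bool(all(a < x for x in e0)),
        "B_between_WL1_WL2": bool(wl[0] < b < wl[1]),
        "C_between_WL2_WL3": bool(wl[1] < c < wl[2]),
        "D_above_all_white_lines": bool(all(d > x for x in wl)),
    }


def mass_for_target_mux(
    mu_rho_above_edge: float, column_diameter_mm: float, target_mux: float = 1.0
) -> float:
    """Element mass (mg) giving attenuation ``µx = target_mux`` along a column.

    For a cylindrical column viewed along its axis, µx depends only on the
    areal density m/A, so

        m = target_mux / (µ/ρ) · π (d/2)²    [g, with d in cm].
    """
    if mu_rho_above_edge <= 0 or column_diameter_mm <= 0 or target_mux <= 0:
        raise ValueError(
            "mu_rho_above_edge, column_diameter_mm and target_mux must all be > 0, got "
            f"({mu_rho_above_edge}, {column_diameter_mm}, {target_mux})"
        )
    radius_cm = 0.05 * column_diameter_mm
    return target_mux / mu_rho_above_edge * np.pi * radius_cm**2 * 1000.0


# ---------------------------------------------------------------------------
# Bundled attenuation anchors and default selenium parameters
# ---------------------------------------------------------------------------

def load_attenuation_anchors() -> pd.DataFrame:
    """Bundled off-edge µ/ρ anchor table (material, energy_keV, mu_rho_cm2_g)."""
    with resources.files("spectoct").joinpath("data/attenuation_anchors.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def anchor_mu_rho(material: str, side: str | None = None) -> float:
    """Look up one anchor value; ``side`` selects the note field substring
    (e.g. ``"above"`` for elemental Se just above its K edge)."""
    tab = load_attenuation_anchors()
    sel = tab[tab["material"] == material]
    if side is not None:
        sel = sel[sel["note"].str.contains(side)]
    if len(sel) != 1:
        raise KeyError(f"anchor lookup ({material!r}, {side!r}) matched {len(sel)} rows")
    return float(sel["mu_rho_cm2_g"].iloc[0])


# Default near-edge parameters of the three Se species, on the pure-Se µ/ρ
# basis (cm² per gram of Se).  E0 / white-line centres are plausible values
# (≈3 eV per oxidation-state step) chosen so the four acquisition energies
# satisfy the bracketing constraints and so the B−A subtraction is dominated
# by Se(0) (higher species still mostly below their edges at B); they are
# not measured values.
SE_EDGE_PARAMS: dict[str, EdgeParams] = {
    "Se(0)": EdgeParams(
        pre_edge_level=7.0, pre_edge_slope=-25.0, edge_energy=12.6525,
        edge_jump=39.0, edge_width=1.5,
        white_line_amplitude=14.0, white_line_center=12.6555, white_line_width=2.0,
    ),
    "Se(IV)": EdgeParams(
        pre_edge_level=7.0, pre_edge_slope=-25.0, edge_energy=12.6590,
        edge_jump=39.0, edge_width=1.2,
        white_line_amplitude=32.0, white_line_center=12.6605, white_line_width=1.8,
    ),
    "Se(VI)": EdgeParams(
        pre_edge_level=7.0, pre_edge_slope=-25.0, edge_energy=12.6625,
        edge_jump=39.0, edge_width=1.2,
        white_line_amplitude=36.0, white_line_center=12.6640, white_line_width=1.8,
    ),
}


def default_energy_grid(step_ev: float = 0.5) -> EnergyGrid:
    """Dense grid spanning the scanned 12.54–12.80 keV Bragg range."""
    return EnergyGrid(np.arange(12.540, 12.800 + 1e-9, step_ev * 1e-3))


def default_acquisition_energies() -> EnergyGrid:
    """The four acquisition energies A–D in keV."""
    return EnergyGrid(np.array(ACQUISITION_ENERGIES_KEV))


def default_se_species(grid: EnergyGrid | None = None) -> dict[str, SpeciesSpectrum]:
    """Spectra of Se(0)/Se(IV)/Se(VI) on the pure-Se basis."""
    if grid is None:
        grid = default_energy_grid()
    return {
        name: edge_spectrum_model(grid, p, name) for name, p in SE_EDGE_PARAMS.items()
    }


def matrix_spectrum(material: str, grid: EnergyGrid | None = None) -> SpeciesSpectrum:
    """Smooth (edge-free) µ/ρ spectrum of a matrix material near 12.66 keV.

    Anchored at the bundled tabulated value and scaled with the
    photoelectric-dominated ``E^-3`` energy dependence — across the 0.26 keV
    span of interest the variation is well under 1 %.
    """
    if grid is None:
        grid = default_energy_grid()
    tab = load_attenuation_anchors()
    sel = tab[(tab["material"] == material) & (~tab["note"].str.contains("edge"))]
    if len(sel) != 1:
        raise KeyError(f"no unique edge-free anchor for material {material!r}")
    e_ref = float(sel["energy_keV"].iloc[0])
    mu_ref = float(sel["mu_rho_cm2_g"].iloc[0])
    mu = mu_ref * (e_ref / grid.energies) ** 3
    return SpeciesSpectrum(material, grid, mu)


# ---------------------------------------------------------------------------
# Spectrum CSV format: header ``energy_keV,<species1>,<species2>,...``
# ---------------------------------------------------------------------------

def write_spectra_csv(path, spectra: list[SpeciesSpectrum]) -> None:
    grid = spectra[0].grid
    for s in spectra[1:]:
        if not np.array_equal(s.grid.energies, grid.energies):
            raise ValueError("all spectra must share one energy grid for CSV export")
    df = pd.DataFrame({"energy_keV": grid.energies})
    for s in spectra:
        df[s.species_name] = s.mu_rho
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> dict[str, SpeciesSpectrum]:
    df = pd.read_csv(path)
    if df.columns[0] != "energy_keV":
        raise ValueError(f"first column must be 'energy_keV', got {df.columns[0]!r}")
    grid = EnergyGrid(df["energy_keV"].to_numpy())
    return {
        c: SpeciesSpectrum(c, grid, df[c].to_numpy()) for c in df.columns[1:]
    }
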