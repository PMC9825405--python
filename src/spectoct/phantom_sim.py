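"""Digital phantom and multi-energy acquisition simulator.

The phantom mirrors the physical test object: a PMMA cuboid
(8.3 × 8.4 × 13.2 mm) drilled with three parallel 2 mm holes, 9.6 mm deep,
each filled over its bottom 7.6 mm with a boron-nitride mixture of one Se
species — Se(0), Se(IV) or Se(VI) — loaded so the above-edge selenium
absorption along the hole axis is µx ≈ 1 (≈ 0.7 mg elemental Se per hole),
with a 2 mm unfilled margin and a tissue-paper cap.

The acquisition model emulates a 256 × 256 photon-counting detector (55 µm
pitch, ≈ 53 µm effective pixel at the sample plane), a flat field of mean
2.6 ph s⁻¹ px⁻¹ with a ±15 % horizontal gradient, darker strip-gap columns
at x = 60 and 180, a handful of defunct pixels, and Poisson counting noise:
200 projections over 360° in 1.8° steps at 100 s each, four photon energies
bracketing the Se white lines, plus 2+2 flat fields of 1000 s.

Internally every phantom component is a sum of separable parts
(2-D density map) × (axial profile), so forward projection needs only one
parallel-beam sinogram per part (via ``skimage.transform.radon``), reused
across energies; projections at θ ≥ 180° are the exact mirror of θ − 180°.
An in-plane fan-beam mode approximates the divergent cone of the real
secondary source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import radon

from ._util import mirror_columns, substream
from .energy_calibration import SpectrometerGeometry
from .materials_spectra import (
    EnergyGrid,
    SpeciesSpectrum,
    default_acquisition_energies,
    default_energy_grid,
    default_se_species,
    matrix_spectrum,
)

__all__ = [
    "PhantomConfig",
    "DigitalPhantom",
    "DetectorModel",
    "AcquisitionPlan",
    "ProjectionStack",
    "build_phantom",
    "default_component_spectra",
    "project_phantom",
    "flat_field_expectation",
    "simulate_flat_field",
    "simulate_counts",
    "simulate_acquisition",
]

SE_COMPONENTS = ("Se(0)+BN", "Se(IV)+BN", "Se(VI)+BN")


class ConfigurationError(ValueError):
    """Raised for geometrically impossible phantom configurations."""


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and loading of the digital phantom.  Lengths in mm,
    densities in g/cm³."""

    cuboid_mm: tuple[float, float, float] = (8.3, 8.4, 13.2)  # (x, y, z)
    hole_diameter_mm: float = 2.0
    hole_depth_mm: float = 9.6
    fill_depth_mm: float = 7.6
    cap_thickness_mm: float = 0.5
    # (x, y) hole centres relative to the cuboid centre
    hole_centers_mm: tuple[tuple[float, float], ...] = (
        (-2.2, -1.5), (2.2, -1.5), (0.0, 1.9),
    )
    pmma_density: float = 1.19
    mix_density: float = 0.5          # packed BN + Se-compound powder
    cellulose_density: float = 0.10   # tissue paper cap
    se_mu_rho_above_edge: float = 46.0  # cm²/g, elemental Se just above K edge
    target_mux: float = 1.0           # above-edge Se absorption along the hole axis
    fill_fraction: float = 1.0
    se_vi_axial_gradient: float = 0.0  # 0 = homogeneous, 1 = full tilt toward cap
    voxel_size_mm: float = 0.053
    shape: tuple[int, int, int] = (256, 256, 256)  # (nz, ny, nx)

    @property
    def se_mass_fraction(self) -> float:
        """Se mass fraction of the mixture giving the target along-axis µx."""
        fill_cm = 0.1 * self.fill_depth_mm
        return self.target_mux / (
            self.se_mu_rho_above_edge * fill_cm * self.mix_density
        )

    @property
    def se_mass_per_hole_mg(self) -> float:
        """Elemental Se mass per hole implied by the target loading."""
        r_cm = 0.05 * self.hole_diameter_mm
        return self.target_mux / self.se_mu_rho_above_edge * np.pi * r_cm**2 * 1000.0


@dataclass(frozen=True)
class _Part:
    """One separable piece of a component: (2-D map) × (axial profile)."""

    xy_density: np.ndarray  # (ny, nx), g/cm³
    z_profile: np.ndarray   # (nz,), dimensionless weight per detector row


@dataclass(frozen=True)
class DigitalPhantom:
    """Voxelised multi-component phantom.

    ``parts`` keeps the separable structure used by the fast projector;
    :meth:`density_map` materialises the full 3-D density of a component.
    Row 0 of the z axis is the top of the field of view.
    """

    voxel_size_mm: float
    shape: tuple[int, int, int]
    parts: dict[str, tuple[_Part, ...]]
    config: PhantomConfig

    @property
    def components(self) -> tuple[str, ...]:
        return tuple(self.parts)

    def density_map(self, component: str) -> np.ndarray:
        """Full (nz, ny, nx) density of one component, g/cm³."""
        out = np.zeros(self.shape, dtype=np.float32)
        for part in self.parts[component]:
            out += part.z_profile[:, None, None].astype(np.float32) * part.xy_density[
                None, :, :
            ].astype(np.float32)
        return out

    def component_mass_mg(self, component: str) -> float:
        """Integrated mass of a component in mg."""
        vox_cm3 = (0.1 * self.voxel_size_mm) ** 3
        total = sum(
            float(p.z_profile.sum()) * float(p.xy_density.sum())
            for p in self.parts[component]
        )
        return total * vox_cm3 * 1000.0


def _interval_coverage(n: int, voxel: float, lo: float, hi: float) -> np.ndarray:
    """Fraction of each voxel [centre ± voxel/2] covered by [lo, hi];
    coordinates are centred: centre of voxel i is (i - (n-1)/2) * voxel."""
    centers = (np.arange(n) - (n - 1) / 2.0) * voxel
    left = centers - voxel / 2.0
    right = centers + voxel / 2.0
    return np.clip((np.minimum(right, hi) - np.maximum(left, lo)) / voxel, 0.0, 1.0)


def _disc_coverage(
    ny: int, nx: int, voxel: float, cx: float, cy: float, radius: float, supersample: int = 4
) -> np.ndarray:
    """Antialiased disc membership (fractional coverage) on the xy grid.

    x maps to columns (rightward), y to rows (upward): row 0 is y_max.
    """
    s = supersample
    off = (np.arange(s) + 0.5) / s - 0.5
    xs = (np.arange(nx)[:, None] - (nx - 1) / 2.0 + off[None, :]) * voxel  # (nx, s)
    ys = ((ny - 1) / 2.0 - np.arange(ny)[:, None] + off[None, :]) * voxel  # (ny, s)
    dx2 = (xs - cx) ** 2  # (nx, s)
    dy2 = (ys - cy) ** 2  # (ny, s)
    inside = (dy2[:, None, :, None] + dx2[None, :, None, :]) <= radius**2
    return inside.mean(axis=(2, 3))


def build_phantom(config: PhantomConfig | None = None) -> DigitalPhantom:
    """Voxelise the phantom into separable component parts.

    Raises :class:`ConfigurationError` for overlapping holes or holes
    outside the cuboid.
    """
    if config is None:
        config = PhantomConfig()
    cx_len, cy_len, cz_len = config.cuboid_mm
    r = 0.5 * config.hole_diameter_mm
    if not 0.0 <= config.fill_fraction <= 1.0:
        raise ConfigurationError(f"fill_fraction must be in [0, 1], got {config.fill_fraction}")
    centers = config.hole_centers_mm
    for i, (x0, y0) in enumerate(centers):
        if abs(x0) + r > cx_len / 2 or abs(y0) + r > cy_len / 2:
            raise ConfigurationError(f"hole {i} at ({x0}, {y0}) mm extends outside the cuboid")
        for j, (x1, y1) in enumerate(centers[:i]):
            if np.hypot(x1 - x0, y1 - y0) < 2 * r:
                raise ConfigurationError(f"holes {j} and {i} overlap")
    if config.hole_depth_mm > cz_len:
        raise ConfigurationError("hole_depth_mm exceeds the cuboid height")
    if config.fill_depth_mm + config.cap_thickness_mm > config.hole_depth_mm:
        raise ConfigurationError("fill + cap exceed the hole depth")

    nz, ny, nx = config.shape
    vox = config.voxel_size_mm

    cuboid_xy = np.outer(
        _interval_coverage(ny, vox, -cy_len / 2, cy_len / 2)[::-1],  # rows: y downward
        _interval_coverage(nx, vox, -cx_len / 2, cx_len / 2),
    )
    discs = [_disc_coverage(ny, nx, vox, x0, y0, r) for (x0, y0) in centers]

    # axial extents (z up, phantom centred): hole drilled from the top
    z_top = cz_len / 2
    z_hole_bottom = z_top - config.hole_depth_mm
    z_fill_top = z_hole_bottom + config.fill_depth_mm
    z_cap_top = z_fill_top + config.cap_thickness_mm

    def zprof(lo: float, hi: float) -> np.ndarray:
        # detector/phantom row 0 is the top: reverse the upward coverage
        return _interval_coverage(nz, vox, lo, hi)[::-1].copy()

    parts: dict[str, tuple[_Part, ...]] = {}
    parts["PMMA"] = (
        _Part(config.pmma_density * cuboid_xy, zprof(-cz_len / 2, z_hole_bottom)),
        _Part(
            config.pmma_density * np.clip(cuboid_xy - sum(discs), 0.0, None),
            zprof(z_hole_bottom, z_top),
        ),
    )
    rho_mix = config.mix_density * config.fill_fraction
    for name, disc in zip(SE_COMPONENTS, discs):
        prof = zprof(z_hole_bottom, z_fill_top)
        if name == "Se(VI)+BN" and config.se_vi_axial_gradient > 0:
            # mass-conserving linear tilt toward the cap end of the fill
            nz_idx = np.arange(nz)
            z_centers = ((nz - 1) / 2.0 - nz_idx) * vox
            mid = 0.5 * (z_hole_bottom + z_fill_top)
            tilt = 1.0 + config.se_vi_axial_gradient * (
                2.0 * (z_centers - mid) / config.fill_depth_mm
            )
            prof = prof * np.clip(tilt, 0.0, None)
        parts[name] = (_Part(rho_mix * disc, prof),)
    parts["tissue"] = (
        _Part(config.cellulose_density * sum(discs), zprof(z_fill_top, z_cap_top)),
    )
    return DigitalPhantom(vox, config.shape, parts, config)


def default_component_spectra(
    config: PhantomConfig | None = None, grid: EnergyGrid | None = None
) -> dict[str, SpeciesSpectrum]:
    """µ/ρ spectra of the five phantom components (per gram of component).

    Mixture spectra combine the Se-species near-edge spectrum with the
    boron-nitride diluent according to the Se mass fraction implied by the
    µx ≈ 1 loading.
    """
    if config is None:
        config = PhantomConfig()
    if grid is None:
        grid = default_energy_grid()
    se = default_se_species(grid)
    bn = matrix_spectrum("BN", grid)
    f = config.se_mass_fraction
    out: dict[str, SpeciesSpectrum] = {
        "PMMA": matrix_spectrum("PMMA", grid),
        "tissue": matrix_spectrum("cellulose", grid),
    }
    for comp, species in zip(SE_COMPONENTS, ("Se(0)", "Se(IV)", "Se(VI)")):
        mu = f * se[species].mu_rho + (1.0 - f) * bn.mu_rho
        out[comp] = SpeciesSpectrum(comp, grid, mu)
    return out


# ---------------------------------------------------------------------------
# Forward projection
# ---------------------------------------------------------------------------

def _part_sinograms(
    phantom: DigitalPhantom, angles_deg: np.ndarray
) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """Parallel-beam sinograms of every part, line integrals in g/cm².

    Only θ mod 180° is projected; θ ≥ 180° views are exact mirrors.
    Returns per component a list of (sinogram (n_angles, nx), z_profile).
    """
    angles = np.asarray(angles_deg, dtype=float)
    base = np.mod(angles, 180.0)
    mirrored = np.mod(angles, 360.0) >= 180.0
    uniq, inv = np.unique(base, return_inverse=True)
    vox_cm = 0.1 * phantom.voxel_size_mm
    out: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for comp, comp_parts in phantom.parts.items():
        lst = []
        for part in comp_parts:
            sino_u = radon(part.xy_density, theta=uniq, circle=True) * vox_cm  # (nx, n_uniq)
            sino = sino_u[:, inv].T  # (n_angles, nx)
            sino[mirrored] = mirror_columns(sino[mirrored], axis=-1)
            lst.append((sino, part.z_profile))
        out[comp] = lst
    return out


def _fanbeam_part_sinograms(
    phantom: DigitalPhantom, angles_deg: np.ndarray, geometry: SpectrometerGeometry
) -> dict[str, list[tuple[np.ndarray, np.ndarray]]]:
    """In-plane fan-beam line integrals from a point secondary source.

    Approximates the divergent cone of the instrument: rays fan out
    horizontally from the secondary source through the rotated object to a
    flat detector.  Axial divergence is neglected.  Breaks the θ / θ+180°
    redundancy that the parallel model has.
    """
    angles = np.radians(np.asarray(angles_deg, dtype=float))
    nz, ny, nx = phantom.shape
    vox_mm = phantom.voxel_size_mm
    ls_px = geometry.secondary_source_to_sample * 1000.0 / vox_mm
    ld_px = (
        geometry.secondary_source_to_detector - geometry.secondary_source_to_sample
    ) * 1000.0 / vox_mm
    # detector columns mapped back to sample-plane pixels via the magnification
    u = (np.arange(nx) - nx // 2) * 1.0  # sample-plane spacing by construction
    step = 0.5  # ray sampling step, px
    half = nx / 2.0 + 2
    out: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {
        comp: [] for comp in phantom.parts
    }
    for comp, comp_parts in phantom.parts.items():
        for part in comp_parts:
            sino = np.zeros((len(angles), nx))
            for ai, th in enumerate(angles):
                c, s = np.cos(th), np.sin(th)
                src = np.array([-ls_px * c, -ls_px * s])  # (x, y) px from centre
                det = np.stack(
                    [ld_px * c - u * s, ld_px * s + u * c], axis=0
                )  # (2, nx)
                d = det - src[:, None]
                norm = np.linalg.norm(d, axis=0)
                d /= norm
                # sample the ray only across the reconstruction circle
                t_mid = np.abs(np.einsum("i,ij->j", -src, d))
                ts = np.arange(-half, half + step, step)
                pts = src[:, None, None] + d[:, :, None] * (t_mid[None, :, None] + ts[None, None, :])
                # (x, y) px → (row, col): row = n//2 - y, col = n//2 + x
                rows = ny // 2 - pts[1]
                cols = nx // 2 + pts[0]
                vals = ndimage.map_coordinates(
                    part.xy_density, [rows, cols], order=1, mode="constant"
                )
                sino[ai] = vals.sum(axis=1) * step * 0.1 * vox_mm
            out[comp].append((sino, part.z_profile))
    return out


def project_phantom(
    phantom: DigitalPhantom,
    spectra: dict[str, SpeciesSpectrum],
    energy_kev: float,
    angles_deg: np.ndarray,
    geometry: SpectrometerGeometry | None = None,
    mode: str = "parallel",
    _part_sinos: dict | None = None,
) -> np.ndarray:
    """Line-integral images µx (dimensionless) for every angle.

    Returns an array of shape (n_angles, n_rows, n_cols) with
    µx = Σ_components (µ/ρ)_c(E) · ∫ ρ_c dl.  ``mode`` is ``"parallel"``
    (default, matching the reconstruction assumption) or ``"cone"`` (the
    fan-beam magnification approximation; needs ``geometry``).

    ``_part_sinos`` lets callers reuse the energy-independent part
    sinograms across energies.
    """
    for comp in phantom.parts:
        if comp not in spectra:
            raise KeyError(f"no spectrum provided for component {comp!r}")
    if _part_sinos is None:
        if mode == "parallel":
            _part_sinos = _part_sinograms(phantom, angles_deg)
        elif mode == "cone":
            if geometry is None:
                geometry = SpectrometerGeometry()
            _part_sinos = _fanbeam_part_sinograms(phantom, angles_deg, geometry)
        else:
            raise ValueError(f"unknown projection mode {mode!r}")
    n_angles = len(np.atleast_1d(angles_deg))
    nz = phantom.shape[0]
    nx = phantom.shape[2]
    mux = np.zeros((n_angles, nz, nx), dtype=np.float32)
    for comp, lst in _part_sinos.items():
        mr = float(spectra[comp](energy_kev))
        for sino, zprof in lst:
            mux += (mr * zprof[None, :, None] * sino[:, None, :]).astype(np.float32)
    return mux


# ---------------------------------------------------------------------------
# Detector and counting statistics
# ---------------------------------------------------------------------------

def _default_defunct(n_rows: int = 256, n_cols: int = 256) -> np.ndarray:
    """Fixed scattered dead pixels (≈ 0.05 %), independent of the run seed."""
    rng = np.random.default_rng(20230107)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    idx = rng.choice(n_rows * n_cols, size=30, replace=False)
    mask.flat[idx] = True
    return mask


@dataclass(frozen=True)
class DetectorModel:
    """Photon-counting detector with flat-field structure."""

    n_rows: int = 256
    n_cols: int = 256
    pixel_pitch_um: float = 55.0
    effective_pixel_um: float = 53.0  # at the sample plane, after magnification
    mean_rate: float = 2.6  # ph / s / px
    gradient_fraction: float = 0.15  # ± relative horizontal span
    gap_columns: tuple[int, ...] = (60, 180)
    gap_attenuation: float = 0.8
    defunct_mask: np.ndarray = field(default_factory=_default_defunct)
    psf_sigma_um: float = 36.0  # system blur (85 µm FWHM ≈ 36 µm sigma)

    def __post_init__(self) -> None:
        if self.mean_rate <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("rates and pitches must be > 0")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be >= 0")
        if any(not 0 <= g < self.n_cols for g in self.gap_columns):
            raise ValueError(f"gap_columns {self.gap_columns} outside detector")
        if self.defunct_mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("defunct_mask shape mismatch")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.effective_pixel_um


@dataclass(frozen=True)
class AcquisitionPlan:
    """Multi-energy rotation protocol."""

    energies: EnergyGrid = field(default_factory=default_acquisition_energies)
    angles_deg: np.ndarray = field(default_factory=lambda: np.arange(0.0, 360.0, 1.8))
    exposure_s: float = 100.0
    flat_exposure_s: float = 1000.0
    n_flats_before: int = 2
    n_flats_after: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "angles_deg", a)
        if a.size and (a.min() < 0 or a.max() >= 360.0):
            raise ValueError("angles must lie in [0, 360)")
        if self.exposure_s <= 0 or self.flat_exposure_s <= 0:
            raise ValueError("exposures must be > 0")


@dataclass
class ProjectionStack:
    """Simulated photon counts per (energy, angle, row, col) plus flats."""

    counts: np.ndarray  # (n_energies, n_angles, n_rows, n_cols)
    flats_before: np.ndarray  # (n_energies, n_flats_before, n_rows, n_cols)
    flats_after: np.ndarray
    plan: AcquisitionPlan
    detector: DetectorModel

    def __post_init__(self) -> None:
        ne, na = len(self.plan.energies), len(self.plan.angles_deg)
        if self.counts.shape[:2] != (ne, na):
            raise ValueError("counts shape inconsistent with the plan")
        if np.issubdtype(self.counts.dtype, np.integer) and self.counts.min() < 0:
            raise ValueError("negative counts")


def flat_field_expectation(detector: DetectorModel, exposure_s: float) -> np.ndarray:
    """Expected flat-field counts: rate × exposure × horizontal gradient ×
    strip-gap attenuation, defunct pixels zeroed."""
    if exposure_s <= 0:
        raise ValueError(f"exposure must be > 0, got {exposure_s}")
    grad = 1.0 + detector.gradient_fraction * np.linspace(-1.0, 1.0, detector.n_cols)
    img = detector.mean_rate * exposure_s * np.broadcast_to(
        grad, (detector.n_rows, detector.n_cols)
    ).copy()
    img[:, list(detector.gap_columns)] *= detector.gap_attenuation
    img[detector.defunct_mask] = 0.0
    return img


def simulate_flat_field(
    detector: DetectorModel,
    exposure_s: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    expectation: bool = False,
) -> np.ndarray:
    """One flat-field image; Poisson-sampled unless ``expectation``."""
    img = flat_field_expectation(detector, exposure_s)
    if expectation:
        return img
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.poisson(img).astype(np.uint32)


def simulate_counts(
    line_integrals: np.ndarray,
    detector: DetectorModel,
    exposure_s: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    expectation: bool = False,
) -> np.ndarray:
    """Beer–Lambert counts for one projection.

    Expected counts = flat-field expectation × exp(−µx), blurred by the
    system PSF, Poisson-sampled (unless ``expectation``), defunct zeroed.
    """
    mux = np.asarray(line_integrals, dtype=float)
    if mux.shape != (detector.n_rows, detector.n_cols):
        raise ValueError(f"line integrals shape {mux.shape} != detector shape")
    if np.any(mux < 0):
        raise ValueError(f"negative µx (min {mux.min():.3g}); line integrals must be >= 0")
    grad = 1.0 + detector.gradient_fraction * np.linspace(-1.0, 1.0, detector.n_cols)
    expected = detector.mean_rate * exposure_s * grad[None, :] * np.exp(-mux)
    if detector.psf_sigma_px > 0:
        expected = ndimage.gaussian_filter(expected, detector.psf_sigma_px)
    expected[:, list(detector.gap_columns)] *= detector.gap_attenuation
    expected[detector.defunct_mask] = 0.0
    if expectation:
        return expected
    if rng is None:
        rng = np.random.default_rng(seed)
    out = rng.poisson(expected).astype(np.uint32)
    return out


def simulate_acquisition(
    phantom: DigitalPhantom,
    spectra: dict[str, SpeciesSpectrum],
    detector: DetectorModel | None = None,
    plan: AcquisitionPlan | None = None,
    geometry: SpectrometerGeometry | None = None,
    mode: str = "parallel",
    expectation: bool = False,
) -> ProjectionStack:
    """Full multi-energy acquisition: projections at every (energy, angle)
    plus before/after flats, all driven by ``plan.seed`` substreams."""
    if detector is None:
        detector = DetectorModel()
    if plan is None:
        plan = AcquisitionPlan()
    if phantom.shape[0] != detector.n_rows or phantom.shape[2] != detector.n_cols:
        raise ValueError(
            f"phantom shape {phantom.shape} inconsistent with detector "
            f"{detector.n_rows}x{detector.n_cols}"
        )
    if mode == "parallel":
        part_sinos = _part_sinograms(phantom, plan.angles_deg)
    elif mode == "cone":
        part_sinos = _fanbeam_part_sinograms(
            phantom, plan.angles_deg, geometry or SpectrometerGeometry()
        )
    else:
        raise ValueError(f"unknown projection mode {mode!r}")

    ne, na = len(plan.energies), len(plan.angles_deg)
    dtype = np.float64 if expectation else np.uint32
    counts = np.empty((ne, na, detector.n_rows, detector.n_cols), dtype=dtype)
    fb = np.empty((ne, plan.n_flats_before, detector.n_rows, detector.n_cols), dtype=dtype)
    fa = np.empty((ne, plan.n_flats_after, detector.n_rows, detector.n_cols), dtype=dtype)
    for ei, energy in enumerate(plan.energies.energies):
        mux = project_phantom(
            phantom, spectra, float(energy), plan.angles_deg, _part_sinos=part_sinos
        )
        for ai in range(na):
            counts[ei, ai] = simulate_counts(
                mux[ai], detector, plan.exposure_s,
                rng=substream(plan.seed, ei, ai), expectation=expectation,
            )
        for k in range(plan.n_flats_before):
            fb[ei, k] = simulate_flat_field(
                detector, plan.flat_exposure_s,
                rng=substream(plan.seed, ei, 10_000 + k), expectation=expectation,
            )
        for k in range(plan.n_flats_after):
            fa[ei, k] = simulate_flat_field(
                detector, plan.flat_exposure_s,
                rng=substream(plan.seed, ei, 20_000 + k), expectation=expectation,
            )
    return ProjectionStack(counts, fb, fa, plan, detector)
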