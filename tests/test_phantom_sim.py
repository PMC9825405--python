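import dataclasses

import numpy as np
import pytest

from spectoct._util import mirror_columns, substream
from spectoct.materials_spectra import EnergyGrid, SpeciesSpectrum
from spectoct.phantom_sim import (
    SE_COMPONENTS,
    AcquisitionPlan,
    ConfigurationError,
    DetectorModel,
    DigitalPhantom,
    PhantomConfig,
    _Part,
    build_phantom,
    default_component_spectra,
    flat_field_expectation,
    project_phantom,
    simulate_acquisition,
    simulate_counts,
    simulate_flat_field,
)


def small_detector(n=32, **kw):
    defaults = dict(
        n_rows=n,
        n_cols=n,
        gap_columns=(),
        defunct_mask=np.zeros((n, n), dtype=bool),
        psf_sigma_um=0.0,
        effective_pixel_um=53.0,
    )
    defaults.update(kw)
    return DetectorModel(**defaults)


def cube_phantom(n=64, vox=0.2, side_mm=6.0, rho=1.0):
    """Single-component homogeneous cuboid with exact analytic attenuation."""
    from spectoct.phantom_sim import _interval_coverage

    xy = np.outer(
        _interval_coverage(n, vox, -side_mm / 2, side_mm / 2),
        _interval_coverage(n, vox, -side_mm / 2, side_mm / 2),
    ) * rho
    z = _interval_coverage(n, vox, -side_mm / 2, side_mm / 2)
    cfg = PhantomConfig(voxel_size_mm=vox, shape=(n, n, n))
    return DigitalPhantom(vox, (n, n, n), {"cube": (_Part(xy, z),)}, cfg)


def flat_spectrum(name="cube", mu_rho=2.0):
    grid = EnergyGrid(np.array([12.5, 12.9]))
    return SpeciesSpectrum(name, grid, np.array([mu_rho, mu_rho]))


class TestBuildPhantom:
    def test_selenium_mass_matches_printed_loading(self):
        """Each hole carries ~0.7 mg of Se (µx ≈ 1 above the K edge)."""
        cfg = PhantomConfig()
        ph = build_phantom(cfg)
        for comp in SE_COMPONENTS:
            se_mass = ph.component_mass_mg(comp) * cfg.se_mass_fraction
            assert se_mass == pytest.approx(0.7, abs=0.05)
            assert se_mass == pytest.approx(cfg.se_mass_per_hole_mg, rel=0.02)

    def test_voxelized_masses_match_analytic_volumes(self):
        """Mass conservation: voxel sums agree with analytic cylinder and
        cuboid volumes to 2 % at 50 µm voxels."""
        cfg = PhantomConfig(voxel_size_mm=0.05, shape=(272, 272, 272))
        ph = build_phantom(cfg)
        r_cm, fill_cm = 0.1, 0.76
        cyl_mass_mg = np.pi * r_cm**2 * fill_cm * cfg.mix_density * 1000
        for comp in SE_COMPONENTS:
            assert ph.component_mass_mg(comp) == pytest.approx(cyl_mass_mg, rel=0.02)
        cub_cm3 = np.prod([0.1 * s for s in cfg.cuboid_mm])
        holes_cm3 = 3 * np.pi * r_cm**2 * 0.96
        pmma_mg = (cub_cm3 - holes_cm3) * cfg.pmma_density * 1000
        assert ph.component_mass_mg("PMMA") == pytest.approx(pmma_mg, rel=0.02)

    def test_zero_fill_fraction_empties_the_holes(self):
        ph = build_phantom(PhantomConfig(fill_fraction=0.0))
        for comp in SE_COMPONENTS:
            assert ph.component_mass_mg(comp) == 0.0
        assert ph.component_mass_mg("PMMA") > 0

    def test_overlapping_holes_rejected(self):
        cfg = PhantomConfig(hole_centers_mm=((0.0, 0.0), (1.0, 0.0), (0.0, 3.0)))
        with pytest.raises(ConfigurationError, match="overlap"):
            build_phantom(cfg)

    def test_hole_outside_cuboid_rejected(self):
        cfg = PhantomConfig(hole_centers_mm=((-3.9, 0.0), (2.2, -1.5), (0.0, 1.9)))
        with pytest.raises(ConfigurationError, match="outside"):
            build_phantom(cfg)

    def test_sevi_axial_gradient_conserves_mass(self):
        flat = build_phantom(PhantomConfig())
        tilted = build_phantom(PhantomConfig(se_vi_axial_gradient=0.8))
        assert tilted.component_mass_mg("Se(VI)+BN") == pytest.approx(
            flat.component_mass_mg("Se(VI)+BN"), rel=1e-4
        )
        # more mass toward the cap (low row index = top)
        m_flat = flat.density_map("Se(VI)+BN").sum(axis=(1, 2))
        m_tilt = tilted.density_map("Se(VI)+BN").sum(axis=(1, 2))
        support = m_flat > 0
        top = np.argmax(support)
        assert m_tilt[top + 2] > m_flat[top + 2]


class TestProjection:
    def test_empty_phantom_projects_to_zero(self):
        ph = cube_phantom(rho=0.0)
        mux = project_phantom(ph, {"cube": flat_spectrum()}, 12.66, np.array([0.0, 33.0]))
        assert np.all(mux == 0)

    def test_homogeneous_cube_axis_aligned_closed_form(self):
        """Axis-aligned ray through a homogeneous cube: µx = (µ/ρ)·ρ·side."""
        ph = cube_phantom(n=64, vox=0.2, side_mm=6.0, rho=1.3)
        mux = project_phantom(ph, {"cube": flat_spectrum(mu_rho=2.0)}, 12.66, np.array([0.0]))
        expected = 2.0 * 1.3 * 0.6  # cm² / g · g / cm³ · cm
        centre = mux[0, 32, 32]
        assert centre == pytest.approx(expected, rel=1e-3)

    def test_selenium_column_attenuation_near_unity_above_edge(self):
        """Along the hole axis at energy D the Se contribution is µx ≈ 1."""
        cfg = PhantomConfig()
        ph = build_phantom(cfg)
        from spectoct.materials_spectra import default_se_species

        dm = ph.density_map("Se(0)+BN")
        areal = dm.sum(axis=0) * 0.1 * cfg.voxel_size_mm  # g/cm²
        se_mux = areal.max() * cfg.se_mass_fraction * default_se_species()["Se(0)"](12.685)
        assert se_mux == pytest.approx(1.0, abs=0.05)

    def test_opposing_views_are_mirror_images(self):
        ph = build_phantom(PhantomConfig(voxel_size_mm=0.212, shape=(64, 64, 64)))
        spectra = default_component_spectra(ph.config)
        angles = np.array([10.0, 190.0])
        mux = project_phantom(ph, spectra, 12.645, angles)
        np.testing.assert_array_equal(mux[1], mirror_columns(mux[0], axis=-1))

    def test_missing_component_spectrum_raises(self):
        ph = cube_phantom()
        with pytest.raises(KeyError, match="cube"):
            project_phantom(ph, {}, 12.66, np.array([0.0]))

    def test_energy_outside_spectrum_grid_raises(self):
        ph = cube_phantom()
        with pytest.raises(ValueError, match="outside"):
            project_phantom(ph, {"cube": flat_spectrum()}, 14.0, np.array([0.0]))


class TestFlatField:
    def test_gradient_spans_printed_rate_bounds(self):
        """±15 % around 2.6 ph/s/px reaches the printed 2.2-3.0 range."""
        det = DetectorModel()
        img = flat_field_expectation(det, exposure_s=1.0)
        rates = np.delete(img, det.gap_columns, axis=1)
        rates = rates[rates > 0]
        assert round(rates.min(), 1) == 2.2
        assert round(rates.max(), 1) == 3.0

    def test_zero_gradient_expectation_is_uniform(self):
        det = small_detector(gradient_fraction=0.0)
        img = simulate_flat_field(det, 10.0, expectation=True)
        np.testing.assert_allclose(img, 2.6 * 10.0)

    def test_poisson_variance_to_mean_ratio(self):
        """Sampled flats are Poisson: var/mean per pixel ≈ 1 over repeats."""
        det = small_detector(n=16)
        reps = np.stack(
            [simulate_flat_field(det, 10.0, rng=substream(5, k)) for k in range(1000)]
        ).astype(float)
        ratio = reps.var(axis=0) / reps.mean(axis=0)
        assert 0.9 < ratio.mean() < 1.1

    def test_gap_columns_darker(self):
        det = DetectorModel()
        img = flat_field_expectation(det, 1.0)
        for g in det.gap_columns:
            assert np.all(img[:, g] < img[:, g - 1])


class TestCounts:
    def test_zero_mux_matches_flat_statistics(self):
        det = small_detector()
        flat = simulate_flat_field(det, 50.0, expectation=True)
        proj = simulate_counts(np.zeros((32, 32)), det, 50.0, expectation=True)
        np.testing.assert_allclose(proj, flat, rtol=1e-12)

    def test_uniform_ln2_halves_the_flat(self):
        det = small_detector(psf_sigma_um=30.0)
        mux = np.full((32, 32), np.log(2.0))
        flat = simulate_counts(np.zeros((32, 32)), det, 50.0, expectation=True)
        proj = simulate_counts(mux, det, 50.0, expectation=True)
        np.testing.assert_allclose(proj, flat / 2.0, rtol=1e-12)

    def test_negative_mux_rejected(self):
        det = small_detector()
        with pytest.raises(ValueError, match="negative"):
            simulate_counts(np.full((32, 32), -0.1), det, 1.0)

    def test_log_ratio_recovers_mux_at_poisson_accuracy(self):
        """-ln(I/I0) errors match first-order Poisson propagation 1/sqrt(N)."""
        det = small_detector()
        mux = np.full((32, 32), 0.8)
        exposure = 200.0
        flat_exp = simulate_counts(np.zeros((32, 32)), det, exposure, expectation=True)
        errs = []
        for k in range(30):
            counts = simulate_counts(mux, det, exposure, rng=substream(11, k))
            est = -np.log(np.maximum(counts, 0.5) / flat_exp)
            errs.append(est - mux)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        predicted = float(np.mean(1.0 / np.sqrt(flat_exp * np.exp(-0.8))))
        assert rmse == pytest.approx(predicted, rel=0.15)


@pytest.fixture(scope="module")
def tiny():
    cfg = PhantomConfig(voxel_size_mm=0.424, shape=(32, 32, 32))
    ph = build_phantom(cfg)
    spectra = default_component_spectra(cfg)
    det = small_detector(n=32)
    plan = AcquisitionPlan(
        energies=EnergyGrid(np.array([12.645, 12.685])),
        angles_deg=np.arange(0.0, 360.0, 30.0),
        exposure_s=100.0,
        seed=3,
    )
    return ph, spectra, det, plan


class TestAcquisition:
    def test_expectation_beer_lambert_round_trip(self, tiny):
        """Noise-free counts invert exactly back to the line integrals."""
        ph, spectra, det, plan = tiny
        stack = simulate_acquisition(ph, spectra, det, plan, expectation=True)
        mux_in = project_phantom(ph, spectra, 12.645, plan.angles_deg)
        flat = flat_field_expectation(det, plan.exposure_s)
        mux_back = -np.log(stack.counts[0] / flat[None])
        np.testing.assert_allclose(mux_back, mux_in, atol=1e-12)

    def test_seeded_runs_bit_reproducible(self, tiny):
        ph, spectra, det, plan = tiny
        a = simulate_acquisition(ph, spectra, det, plan)
        b = simulate_acquisition(ph, spectra, det, plan)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.flats_before, b.flats_before)

    def test_different_seeds_decorrelate(self, tiny):
        ph, spectra, det, plan = tiny
        a = simulate_acquisition(ph, spectra, det, plan)
        c = simulate_acquisition(
            ph, spectra, det, dataclasses.replace(plan, seed=99)
        )
        assert np.any(a.counts != c.counts)

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            AcquisitionPlan(angles_deg=np.array([0.0, 361.0]))
        with pytest.raises(ValueError):
            AcquisitionPlan(exposure_s=0.0)
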