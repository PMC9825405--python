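import numpy as np
import pytest
from scipy.special import erf

from spectoct.phantom_sim import build_phantom, default_component_spectra
from spectoct.pipeline import ROI_COMPONENTS, default_rois, roi_slices
from spectoct.speciation import (
    DecompositionMatrix,
    decompose,
    estimate_C_from_rois,
    estimate_resolution_esf,
    kedge_subtract,
)


def synthetic_tomograms(
    config=None, energies=(12.645, 12.658, 12.662, 12.685), rows=slice(28, 34)
):
    """Ideal linear-attenuation maps y(E) = Σ_c (µ/ρ)_c(E) ρ_c built straight
    from the phantom ground truth (no imaging chain).  ``rows`` must lie
    inside the filled section of the holes."""
    from spectoct.config import preset

    cfg = (config or preset("smoke")).phantom
    ph = build_phantom(cfg)
    spectra = default_component_spectra(cfg)
    maps = {c: ph.density_map(c)[rows] for c in ph.components}
    y = [
        sum(spectra[c](e) * maps[c] for c in ph.components) for e in energies
    ]
    return ph, maps, y


class TestKEdgeSubtract:
    def test_identical_tomograms_give_zero_maps(self):
        t = np.random.default_rng(0).random((2, 16, 16))
        diffs = kedge_subtract([t, t.copy(), t.copy()])
        assert len(diffs) == 2
        for d in diffs:
            np.testing.assert_array_equal(d, 0.0)

    def test_single_tomogram_gives_empty_list(self):
        assert kedge_subtract([np.zeros((4, 4))]) == []

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="aligned"):
            kedge_subtract([np.zeros((4, 4)), np.zeros((5, 4))])

    def test_adjacent_differences_isolate_but_do_not_separate_species(self):
        """B−A is dominated by the Se(0) edge, yet the other species leave
        residuals — plain subtraction cannot fully unmix them."""
        from spectoct.config import preset

        cfg = preset("smoke")
        ph, maps, y = synthetic_tomograms(cfg)
        diffs = kedge_subtract(y)
        b_minus_a = diffs[0]
        rois = default_rois(cfg, n_slices=b_minus_a.shape[0])
        mean_in = {
            label: float(b_minus_a[roi_slices(box)].mean())
            for label, box in rois.items()
        }
        assert mean_in["Se(0)"] > mean_in["Se(IV)"] > 0
        assert mean_in["Se(VI)"] > 0  # residual cross-talk
        assert mean_in["Se(0)"] > 5 * abs(mean_in["matrix"])


class TestMatrixEstimation:
    def test_noiseless_rois_recover_spectra_columns(self):
        """ROI sums of ideal tomograms are proportional to the component
        spectra sampled at the four energies.  Uses the full-resolution
        geometry so the default ROI boxes are strictly interior to the
        holes (no partial-coverage voxels carrying matrix signal)."""
        from spectoct.config import preset

        cfg = preset("full-scale")
        energies = (12.645, 12.658, 12.662, 12.685)
        ph, maps, y = synthetic_tomograms(cfg, energies, rows=slice(100, 103))
        rois = {
            label: roi_slices(b) for label, b in default_rois(cfg, y[0].shape[0]).items()
        }
        mat = estimate_C_from_rois(y, rois, normalize_columns=True)
        spectra = default_component_spectra(cfg.phantom)
        for ci, label in enumerate(mat.component_labels):
            truth = np.array([spectra[ROI_COMPONENTS[label]](e) for e in energies])
            truth = truth / np.linalg.norm(truth)
            np.testing.assert_allclose(mat.C[:, ci], truth, rtol=1e-6)

    def test_matrix_roi_column_is_nearly_energy_flat(self):
        from spectoct.config import preset

        cfg = preset("smoke")
        ph, maps, y = synthetic_tomograms(cfg)
        rois = {
            label: roi_slices(b) for label, b in default_rois(cfg, y[0].shape[0]).items()
        }
        mat = estimate_C_from_rois(y, rois)
        pmma = mat.C[:, list(mat.component_labels).index("matrix")]
        assert np.ptp(pmma) / pmma.mean() < 0.02

    def test_identical_rois_trigger_rank_deficiency_error(self):
        y = [np.random.default_rng(k).random((4, 16, 16)) for k in range(4)]
        roi = (slice(0, 2), slice(2, 6), slice(2, 6))
        with pytest.raises(ValueError, match="collinear|rank"):
            estimate_C_from_rois(y, {"a": roi, "b": roi})

    def test_empty_roi_raises(self):
        y = [np.zeros((2, 8, 8))]
        with pytest.raises(ValueError, match="empty"):
            estimate_C_from_rois(y, {"a": (slice(0, 0), slice(0, 4), slice(0, 4))})

    def test_condition_number_reported(self):
        mat = DecompositionMatrix(
            np.array([[1.0, 0.0], [0.0, 0.5], [0.1, 0.1]]), ("a", "b"), ("e1", "e2", "e3")
        )
        assert mat.condition_number > 1.0
        assert not mat.ill_conditioned


class TestDecompose:
    def test_identity_matrix_returns_input(self):
        y = [np.random.default_rng(k).random((8, 8)) for k in range(3)]
        mat = DecompositionMatrix(np.eye(3), ("a", "b", "c"), ("e1", "e2", "e3"))
        out = decompose(y, mat)
        for k in range(3):
            np.testing.assert_allclose(out.x[k], y[k], atol=1e-12)

    def test_construct_and_recover_exactly(self):
        rng = np.random.default_rng(4)
        C = np.array(
            [[2.0, 1.9, 1.8, 1.7], [2.0, 3.1, 2.0, 1.9], [2.0, 2.9, 3.3, 2.1], [2.0, 2.8, 3.0, 3.4]]
        )
        x_true = rng.random((4, 12, 12))
        y = list(np.einsum("ec,cij->eij", C, x_true))
        mat = DecompositionMatrix(C, ("m", "0", "4", "6"), ("A", "B", "C", "D"))
        out = decompose(y, mat)
        assert np.max(np.abs(out.x - x_true)) <= 1e-8

    def test_square_recombination_residual_vanishes(self):
        rng = np.random.default_rng(5)
        C = rng.random((3, 3)) + np.eye(3)
        y = [rng.random((6, 6)) for _ in range(3)]
        mat = DecompositionMatrix(C, ("a", "b", "c"), ("1", "2", "3"))
        out = decompose(y, mat)
        assert np.max(np.abs(out.residual)) <= 1e-10

    def test_column_scale_covariance(self):
        rng = np.random.default_rng(6)
        C = rng.random((4, 3)) + np.eye(4, 3)
        y = [rng.random((5, 5)) for _ in range(4)]
        mat = DecompositionMatrix(C.copy(), ("a", "b", "c"), ("1", "2", "3", "4"))
        out = decompose(y, mat)
        k = 3.0
        C2 = C.copy()
        C2[:, 1] *= k
        out2 = decompose(y, DecompositionMatrix(C2, ("a", "b", "c"), ("1", "2", "3", "4")))
        np.testing.assert_allclose(out2.x[1], out.x[1] / k, rtol=1e-9)
        np.testing.assert_allclose(out2.x[0], out.x[0], rtol=1e-9)

    def test_wrong_number_of_tomograms_raises(self):
        mat = DecompositionMatrix(np.eye(3), ("a", "b", "c"), ("1", "2", "3"))
        with pytest.raises(ValueError, match="tomograms"):
            decompose([np.zeros((4, 4))] * 2, mat)


def blurred_step_image(sigma_px, n_rows=12, width=64, edge=30.3):
    x = np.arange(width)
    esf = 0.5 * (1.0 + erf((x - edge) / (sigma_px * np.sqrt(2.0))))
    return np.tile(esf, (n_rows, 1))


class TestResolution:
    @pytest.mark.parametrize("sigma_px", [1.0, 2.0, 3.0, 4.0, 5.0])
    def test_known_gaussian_blur_recovered_within_two_percent(self, sigma_px):
        img = blurred_step_image(sigma_px)
        est = estimate_resolution_esf(img, (0, 12, 0, 64), pixel_size_um=55.0)
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_px * 55.0
        assert est.mean_fwhm_um == pytest.approx(expected, rel=0.02)
        assert est.n_rows_failed == 0

    def test_known_blur_in_sample_plane_pixels(self):
        """σ = 2 px at 55 µm pitch: FWHM = 2.355·2·55 ≈ 259 µm."""
        img = blurred_step_image(2.0)
        est = estimate_resolution_esf(img, (0, 12, 0, 64), pixel_size_um=55.0)
        assert est.mean_fwhm_um == pytest.approx(259.0, rel=0.02)

    def test_ideal_step_hits_sampling_floor(self):
        x = np.arange(64)
        img = np.tile((x >= 30).astype(float), (10, 1))
        est = estimate_resolution_esf(img, (0, 10, 0, 64), pixel_size_um=55.0)
        assert est.mean_fwhm_px <= 2.0
        assert est.resolution_limited

    def test_falling_edge_handled(self):
        img = 1.0 - blurred_step_image(2.0)
        est = estimate_resolution_esf(img, (0, 12, 0, 64), pixel_size_um=55.0)
        assert est.mean_fwhm_um == pytest.approx(259.0, rel=0.02)

    def test_mean_and_standard_error_definitions(self):
        rng = np.random.default_rng(8)
        img = blurred_step_image(2.0, n_rows=20) + 0.01 * rng.normal(size=(20, 64))
        est = estimate_resolution_esf(img, (0, 20, 0, 64), pixel_size_um=55.0)
        assert est.mean_fwhm_um == pytest.approx(est.per_row_fwhm_um.mean())
        assert est.standard_error_um == pytest.approx(
            est.per_row_fwhm_um.std(ddof=1) / np.sqrt(est.n_rows_used)
        )

    def test_too_few_rows_raises(self):
        img = blurred_step_image(2.0, n_rows=3)
        with pytest.raises(ValueError, match="5 profiles"):
            estimate_resolution_esf(img, (0, 3, 0, 64), pixel_size_um=55.0)

    def test_unfittable_profiles_raise_after_exclusion(self):
        img = np.zeros((8, 16))  # flat profiles carry no edge at all
        with pytest.raises(ValueError, match="at least 3"):
            estimate_resolution_esf(img, (0, 8, 0, 16), pixel_size_um=55.0)
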