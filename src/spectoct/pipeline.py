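"""End-to-end pipeline: simulate → preprocess → reconstruct → decompose →
metrology, with a manifest tying every artifact to the configuration and
seed that produced it."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import io as sio
from .config import RunConfig
from .materials_spectra import default_energy_grid, read_spectra_csv
from .phantom_sim import (
    AcquisitionPlan,
    DigitalPhantom,
    ProjectionStack,
    build_phantom,
    default_component_spectra,
    simulate_acquisition,
)
from .recon import (
    Sinogram,
    Tomogram,
    assemble_sinogram,
    average_flats,
    correct_sinogram_background,
    fbp_reconstruct,
    flat_field_correct,
    half_sinogram_check,
    repair_defunct_pixels,
)
from .speciation import (
    decompose,
    estimate_C_from_rois,
    estimate_resolution_esf,
    kedge_subtract,
)

__all__ = [
    "PipelineError",
    "acquisition_time",
    "total_acquisition_time",
    "default_recon_rows",
    "default_air_ranges",
    "default_rois",
    "validation_rois",
    "recovery_correlations",
    "default_esf_edge_box",
    "preprocess_stack",
    "reconstruct_energy",
    "run_pipeline",
]

#: analysis component label → phantom component holding its ground truth
ROI_COMPONENTS = {
    "matrix": "PMMA",
    "Se(0)": "Se(0)+BN",
    "Se(IV)": "Se(IV)+BN",
    "Se(VI)": "Se(VI)+BN",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and parameter."""


def acquisition_time(plan: AcquisitionPlan) -> float:
    """Duration of one energy step in hours (projections only; flats are
    reported separately by :func:`total_acquisition_time`)."""
    return len(plan.angles_deg) * plan.exposure_s / 3600.0


def total_acquisition_time(plan: AcquisitionPlan) -> float:
    """Hours for the whole protocol: every energy's projection stack plus
    one set of before/after flats."""
    n_flats = plan.n_flats_before + plan.n_flats_after
    return (
        len(plan.energies) * len(plan.angles_deg) * plan.exposure_s
        + n_flats * plan.flat_exposure_s
    ) / 3600.0


# ---------------------------------------------------------------------------
# Geometry-derived defaults
# ---------------------------------------------------------------------------

def _row_of_z(z_mm: float, nz: int, vox: float) -> int:
    return int(round((nz - 1) / 2.0 - z_mm / vox))


def default_recon_rows(config: RunConfig, n: int = 5) -> tuple[int, ...]:
    """Detector rows spread across the filled section of the holes."""
    ph = config.phantom
    nz = ph.shape[0]
    z_top = ph.cuboid_mm[2] / 2.0
    z_bot = z_top - ph.hole_depth_mm
    z_fill_top = z_bot + ph.fill_depth_mm
    r0 = _row_of_z(z_fill_top - 0.5, nz, ph.voxel_size_mm)
    r1 = _row_of_z(z_bot + 0.5, nz, ph.voxel_size_mm)
    return tuple(int(r) for r in np.linspace(r0, r1, n).round())


def default_air_ranges(config: RunConfig) -> tuple[tuple[int, int], ...]:
    """Lateral air margins outside the rotating phantom's support."""
    ph = config.phantom
    n = ph.shape[2]
    half_diag_px = 0.5 * np.hypot(ph.cuboid_mm[0], ph.cuboid_mm[1]) / ph.voxel_size_mm
    inner = n // 2 - int(np.ceil(half_diag_px)) - 2
    inner = max(inner, 2)
    return ((1, inner), (n - inner, n - 1))


def default_rois(config: RunConfig, n_slices: int) -> dict[str, list]:
    """Axis-aligned boxes, one per analysis component, from the phantom
    geometry: a box inside each Se hole plus one in pure PMMA.

    The z-range spans the first half of the reconstructed slices; the
    second half is held out as validation voxels for the recovery check
    (see :func:`recovery_correlations`), so the attenuation matrix and its
    validation never share data.
    """
    ph = config.phantom
    nz, ny, nx = ph.shape
    vox = ph.voxel_size_mm
    half = max(2, int(round(0.55 * 0.5 * ph.hole_diameter_mm / vox)))
    centers = {"matrix": (0.0, -2.9)}
    for label, (x, y) in zip(["Se(0)", "Se(IV)", "Se(VI)"], ph.hole_centers_mm):
        centers[label] = (x, y)
    rois = {}
    z1 = max(1, int(np.ceil(n_slices / 2)))
    for label, (x, y) in centers.items():
        row = int(round((ny - 1) / 2.0 - y / vox))
        col = int(round((nx - 1) / 2.0 + x / vox))
        rois[label] = [
            [0, z1],
            [row - half, row + half + 1],
            [col - half, col + half + 1],
        ]
    return rois


def validation_rois(rois: dict[str, list], n_slices: int) -> dict[str, list] | None:
    """Held-out counterparts of the estimation ROIs: the same lateral boxes
    over the slices the estimation z-ranges leave free.  ``None`` when the
    estimation ROIs already cover every slice."""
    out = {}
    for label, ((z0, z1), yy, xx) in ((k, v) for k, v in rois.items()):
        if z1 >= n_slices:
            return None
        out[label] = [[z1, n_slices], list(yy), list(xx)]
    return out


def recovery_correlations(
    phantom: DigitalPhantom,
    components_x: np.ndarray,
    component_labels: tuple[str, ...],
    val_rois: dict[str, list],
    recon_rows: tuple[int, ...],
) -> dict[str, float]:
    """Per-component Pearson correlation between held-out ROI means of the
    decomposed maps and the ground-truth component densities.

    ROI averaging beats the severe per-voxel photon noise down; the held-out
    ROIs are disjoint from those that built the attenuation matrix, so the
    agreement is a genuine recovery measure, not an algebraic identity.
    """
    rows = list(recon_rows)
    out = {}
    for ci, label in enumerate(component_labels):
        truth_map = phantom.density_map(ROI_COMPONENTS[label])[rows]
        est, tru = [], []
        for box in val_rois.values():
            sl = roi_slices(box)
            est.append(float(components_x[ci][sl].mean()))
            tru.append(float(truth_map[sl].mean()))
        out[label] = float(np.corrcoef(est, tru)[0, 1])
    return out


def roi_slices(box: list) -> tuple[slice, slice, slice]:
    """`[[z0,z1],[y0,y1],[x0,x1]]` (0-based, half-open) → slice tuple."""
    (z0, z1), (y0, y1), (x0, x1) = box
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1))


def default_esf_edge_box(config: RunConfig) -> tuple[int, int, int, int]:
    """Box over the phantom's lateral edge in the solid-PMMA band below the
    holes (the projection's lower-left corner)."""
    ph = config.phantom
    nz, _, nx = ph.shape
    vox = ph.voxel_size_mm
    z_bot = ph.cuboid_mm[2] / 2.0 - ph.hole_depth_mm
    r0 = _row_of_z(z_bot - 0.3, nz, vox)
    r1 = min(_row_of_z(-ph.cuboid_mm[2] / 2.0 + 0.5, nz, vox), nz - 1)
    edge_col = (nx - 1) / 2.0 - 0.5 * ph.cuboid_mm[0] / vox
    half = int(np.clip(round(0.55 / vox), 5, 11))
    c0 = max(int(edge_col) - half, 0)
    c1 = min(int(edge_col) + half + 2, nx)
    return (r0, r1, c0, c1)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def preprocess_stack(
    stack: ProjectionStack,
    recon_rows: tuple[int, ...],
    air_ranges: tuple[tuple[int, int], ...],
    count_floor: float = 0.5,
    keep_projection: tuple[int, int] | None = None,
) -> dict:
    """Repair, flat-field and background-correct; return per-energy
    sinograms for the requested detector rows.

    ``keep_projection`` (energy index, angle index) optionally returns that
    corrected µx projection image for metrology.
    """
    det = stack.detector
    plan = stack.plan
    ratio = plan.exposure_s / plan.flat_exposure_s
    sinograms: dict[float, dict[int, Sinogram]] = {}
    reports = []
    kept = None
    for ei, energy in enumerate(plan.energies.energies):
        flat = average_flats(
            np.concatenate([stack.flats_before[ei], stack.flats_after[ei]])
        )
        flat = repair_defunct_pixels(flat, det.defunct_mask)
        mux_rows = np.empty(
            (len(plan.angles_deg), len(recon_rows), det.n_cols), dtype=np.float64
        )
        for ai in range(len(plan.angles_deg)):
            proj = repair_defunct_pixels(stack.counts[ei, ai], det.defunct_mask)
            mux = flat_field_correct(proj, flat, ratio, count_floor)
            mux_rows[ai] = mux[list(recon_rows), :]
            if keep_projection == (ei, ai):
                kept = mux
        per_row = {}
        for ri, row in enumerate(recon_rows):
            sino = Sinogram(
                mux_rows[:, ri, :],
                plan.angles_deg,
                row,
                det.effective_pixel_um / 1000.0,
            )
            sino, rep = correct_sinogram_background(sino, air_ranges)
            per_row[row] = sino
            reports.append({"energy_kev": float(energy), "row": row, **{
                k: v for k, v in rep.items() if k != "air_columns"
            }})
        sinograms[float(energy)] = per_row
    return {"sinograms": sinograms, "reports": reports, "projection_mux": kept}


def reconstruct_energy(
    sinograms_by_row: dict[int, Sinogram],
    energy_kev: float,
    filter_name: str = "ramp",
) -> Tomogram:
    rows = tuple(sorted(sinograms_by_row))
    slices = np.stack(
        [fbp_reconstruct(sinograms_by_row[r], filter_name=filter_name) for r in rows]
    )
    first = sinograms_by_row[rows[0]]
    return Tomogram(slices, first.pixel_size_mm, energy_kev, rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute the full chain and (optionally) write all artifacts.

    Returns a results dictionary with the phantom, tomograms, decomposition
    and metrology; with ``write=True`` every output lands in
    ``config.output_dir`` together with the echoed configuration and a
    checksummed manifest.  Identical configurations (same seed) produce
    bit-identical outputs.
    """
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    # --- phantom + spectra -------------------------------------------------
    try:
        phantom = build_phantom(config.phantom)
    except Exception as exc:
        raise PipelineError(f"stage 'phantom': {exc}") from exc
    if config.spectra_csv is not None:
        p = Path(config.spectra_csv)
        if not p.exists():
            raise PipelineError(f"stage 'spectra': spectra file not found: {p}")
        spectra = read_spectra_csv(p)
        missing = set(phantom.components) - set(spectra)
        if missing:
            raise PipelineError(f"stage 'spectra': no spectrum for components {sorted(missing)}")
    else:
        spectra = default_component_spectra(config.phantom, default_energy_grid())

    # --- simulate ----------------------------------------------------------
    try:
        stack = simulate_acquisition(
            phantom,
            spectra,
            config.detector,
            config.plan,
            geometry=config.geometry,
            mode=config.mode,
            expectation=config.expectation,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'simulate': {exc}") from exc
    if write and not config.expectation:
        sio.save_stack_h5(out / "acquisition.h5", stack)

    # --- preprocess --------------------------------------------------------
    recon_rows = config.recon_rows or default_recon_rows(config)
    air_ranges = config.air_ranges or default_air_ranges(config)
    try:
        pre = preprocess_stack(
            stack, recon_rows, air_ranges, config.count_floor, keep_projection=(0, 0)
        )
    except Exception as exc:
        raise PipelineError(f"stage 'preprocess': {exc}") from exc

    # --- reconstruct -------------------------------------------------------
    try:
        tomograms = {
            e: reconstruct_energy(per_row, e, config.filter_name)
            for e, per_row in pre["sinograms"].items()
        }
        energies = sorted(tomograms)
        mid_row = recon_rows[len(recon_rows) // 2]
        half_check = half_sinogram_check(
            pre["sinograms"][energies[0]][mid_row], config.filter_name
        )
    except Exception as exc:
        raise PipelineError(f"stage 'reconstruct': {exc}") from exc

    # --- speciation --------------------------------------------------------
    y = [tomograms[e].slices for e in energies]
    rois = config.rois or default_rois(config, n_slices=len(recon_rows))
    try:
        diffs = kedge_subtract(y)
        matrix = estimate_C_from_rois(
            y,
            {c: roi_slices(b) for c, b in rois.items()},
            energy_labels=tuple(f"{e:.6g}" for e in energies),
        )
        components = decompose(y, matrix)
        val_rois = validation_rois(rois, len(recon_rows))
        recovery = (
            recovery_correlations(
                phantom, components.x, matrix.component_labels, val_rois, recon_rows
            )
            if val_rois
            else None
        )
    except Exception as exc:
        raise PipelineError(f"stage 'decompose': {exc}") from exc

    # --- metrology ---------------------------------------------------------
    edge_box = config.esf_edge_box or default_esf_edge_box(config)
    try:
        resolution = estimate_resolution_esf(
            pre["projection_mux"], edge_box, config.detector.effective_pixel_um
        )
    except Exception as exc:
        raise PipelineError(f"stage 'resolution': {exc}") from exc

    results = {
        "phantom": phantom,
        "stack": stack,
        "tomograms": tomograms,
        "half_sinogram": {
            k: v for k, v in half_check.items() if not k.startswith("slice")
        },
        "kedge_differences": diffs,
        "matrix": matrix,
        "components": components,
        "recovery": recovery,
        "resolution": resolution,
        "rois": rois,
        "recon_rows": recon_rows,
        "preprocess_reports": pre["reports"],
    }

    if write:
        for e in energies:
            tag = f"{e:.6g}".replace(".", "p")
            sio.tomogram_to_tiff(out / f"tomogram_{tag}keV.tif", tomograms[e].slices)
        for ci, label in enumerate(matrix.component_labels):
            tag = label.replace("(", "").replace(")", "").replace("/", "-")
            sio.tomogram_to_tiff(out / f"component_{tag}.tif", components.x[ci])
        sio.write_c_matrix_csv(out / "C_matrix.csv", matrix)
        sio.write_metrology_csv(out / "resolution.csv", resolution)
        log = {
            "seed": config.seed,
            "recon_rows": list(recon_rows),
            "air_ranges": [list(r) for r in air_ranges],
            "rois": rois,
            "esf_edge_box": list(edge_box),
            "half_sinogram_normalized_rms": half_check["normalized_rms"],
            "condition_number": matrix.condition_number,
            "recovery_correlations": recovery,
            "mean_fwhm_um": resolution.mean_fwhm_um,
            "standard_error_um": resolution.standard_error_um,
            "preprocess_reports": pre["reports"],
        }
        (out / "processing_report.json").write_text(json.dumps(log, indent=1))
        files = sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        import numpy, scipy, skimage  # noqa: PLC0415

        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "scikit-image": skimage.__version__,
            },
            "files": {name: _sha256(out / name) for name in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        results["manifest"] = manifest
    return results
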