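"""File formats: HDF5 acquisition layout, multi-page float TIFF, CSV tables.

HDF5 layout (one file per acquisition):

    /projections/<energy_keV>   angle × row × col counts
    /flats/<energy_keV>         flat images (before then after), same shape
    /angles                     projection angles, degrees
    /energies                   photon energies, keV
    /meta                       attrs: exposures, seed, detector parameters

TIFF stacks are 32-bit float, one page per angle or slice, written with
tifffile; CSV carries spectra, the decomposition matrix and metrology.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import tifffile

from .materials_spectra import EnergyGrid
from .phantom_sim import AcquisitionPlan, DetectorModel, ProjectionStack
from .speciation import DecompositionMatrix, ResolutionEstimate

__all__ = [
    "save_stack_h5",
    "load_stack_h5",
    "projections_to_tiff",
    "tomogram_to_tiff",
    "load_projections_tiff",
    "write_c_matrix_csv",
    "read_c_matrix_csv",
    "write_metrology_csv",
]


def _ekey(e: float) -> str:
    return f"{e:.6g}"


def save_stack_h5(path, stack: ProjectionStack, extra_meta: dict | None = None) -> None:
    plan, det = stack.plan, stack.detector
    with h5py.File(path, "w") as f:
        gp = f.create_group("projections")
        gf = f.create_group("flats")
        for ei, e in enumerate(plan.energies.energies):
            gp.create_dataset(_ekey(e), data=stack.counts[ei], compression="gzip", track_times=False)
            flats = np.concatenate([stack.flats_before[ei], stack.flats_after[ei]])
            gf.create_dataset(_ekey(e), data=flats, compression="gzip", track_times=False)
        f.create_dataset("angles", data=plan.angles_deg, track_times=False)
        f.create_dataset("energies", data=plan.energies.energies, track_times=False)
        meta = f.create_group("meta")
        meta.attrs["exposure_s"] = plan.exposure_s
        meta.attrs["flat_exposure_s"] = plan.flat_exposure_s
        meta.attrs["n_flats_before"] = plan.n_flats_before
        meta.attrs["n_flats_after"] = plan.n_flats_after
        meta.attrs["seed"] = plan.seed
        for k in (
            "n_rows", "n_cols", "pixel_pitch_um", "effective_pixel_um",
            "mean_rate", "gradient_fraction", "gap_attenuation", "psf_sigma_um",
        ):
            meta.attrs[k] = getattr(det, k)
        meta.attrs["gap_columns"] = list(det.gap_columns)
        meta.create_dataset("defunct_mask", data=det.defunct_mask, track_times=False)
        if extra_meta:
            meta.attrs["extra"] = json.dumps(extra_meta)


def load_stack_h5(path) -> ProjectionStack:
    with h5py.File(path, "r") as f:
        energies = f["energies"][()]
        angles = f["angles"][()]
        meta = f["meta"]
        det = DetectorModel(
            n_rows=int(meta.attrs["n_rows"]),
            n_cols=int(meta.attrs["n_cols"]),
            pixel_pitch_um=float(meta.attrs["pixel_pitch_um"]),
            effective_pixel_um=float(meta.attrs["effective_pixel_um"]),
            mean_rate=float(meta.attrs["mean_rate"]),
            gradient_fraction=float(meta.attrs["gradient_fraction"]),
            gap_columns=tuple(int(g) for g in meta.attrs["gap_columns"]),
            gap_attenuation=float(meta.attrs["gap_attenuation"]),
            defunct_mask=meta["defunct_mask"][()].astype(bool),
            psf_sigma_um=float(meta.attrs["psf_sigma_um"]),
        )
        nb = int(meta.attrs["n_flats_before"])
        na = int(meta.attrs["n_flats_after"])
        plan = AcquisitionPlan(
            energies=EnergyGrid(np.asarray(energies)),
            angles_deg=np.asarray(angles),
            exposure_s=float(meta.attrs["exposure_s"]),
            flat_exposure_s=float(meta.attrs["flat_exposure_s"]),
            n_flats_before=nb,
            n_flats_after=na,
            seed=int(meta.attrs["seed"]),
        )
        counts = np.stack([f["projections"][_ekey(e)][()] for e in energies])
        flats = np.stack([f["flats"][_ekey(e)][()] for e in energies])
    return ProjectionStack(counts, flats[:, :nb], flats[:, nb:], plan, det)


def projections_to_tiff(path, counts_one_energy: np.ndarray) -> None:
    """Multi-page float32 TIFF, one page per projection angle."""
    tifffile.imwrite(path, counts_one_energy.astype(np.float32), photometric="minisblack")


def tomogram_to_tiff(path, slices: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(slices, dtype=np.float32), photometric="minisblack")


def load_projections_tiff(tiff_path, angles_csv_path) -> tuple[np.ndarray, np.ndarray]:
    """Projection stack from a multi-page TIFF plus an angle-list CSV
    (single column ``angle_deg``)."""
    stack = tifffile.imread(tiff_path)
    angles = pd.read_csv(angles_csv_path)["angle_deg"].to_numpy(dtype=float)
    if stack.shape[0] != angles.size:
        raise ValueError(
            f"{stack.shape[0]} TIFF pages but {angles.size} angles in the list"
        )
    return stack, angles


def write_c_matrix_csv(path, matrix: DecompositionMatrix) -> None:
    df = pd.DataFrame(
        matrix.C, index=list(matrix.energy_labels), columns=list(matrix.component_labels)
    )
    with open(path, "w") as fh:
        fh.write(f"# condition_number = {matrix.condition_number:.6g}\n")
        df.to_csv(fh, index_label="energy")


def read_c_matrix_csv(path) -> DecompositionMatrix:
    df = pd.read_csv(path, comment="#", index_col="energy")
    return DecompositionMatrix(
        df.to_numpy(dtype=float), tuple(df.columns), tuple(str(i) for i in df.index)
    )


def write_metrology_csv(path, est: ResolutionEstimate) -> None:
    df = pd.DataFrame({"fwhm_um": est.per_row_fwhm_um})
    with open(path, "w") as fh:
        fh.write(
            f"# mean_fwhm_um = {est.mean_fwhm_um:.4g}, "
            f"standard_error_um = {est.standard_error_um:.4g}, "
            f"n_rows_used = {est.n_rows_used}, n_rows_failed = {est.n_rows_failed}\n"
        )
        df.to_csv(fh, index_label="row")
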