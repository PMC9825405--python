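"""Preprocessing and parallel-beam filtered back projection.

The chain mirrors the instrument's data reduction: defunct-pixel repair by
neighbourhood medians, flat-field normalisation µx = −ln(I/I₀), per-row
sinogram assembly, removal of the slowly varying stray background by a
per-angle linear fit over the air margins, and ramp-filtered back projection
of the full 360° stack under the parallel-beam assumption.  A half-sinogram
consistency check quantifies how well that assumption holds.

Conventions (used everywhere): images are indexed (row, col) from the top
left, 0-based; detector row index = axial slice index; rotation angles are
counterclockwise viewed from above; the rotation axis projects to detector
column ``n_cols // 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import iradon

from ._util import mirror_columns

__all__ = [
    "Sinogram",
    "Tomogram",
    "repair_defunct_pixels",
    "average_flats",
    "flat_field_correct",
    "assemble_sinogram",
    "correct_sinogram_background",
    "fbp_reconstruct",
    "estimate_rotation_center",
    "half_sinogram_check",
]


@dataclass(frozen=True)
class Sinogram:
    """µx line integrals of one detector row versus projection angle."""

    values: np.ndarray  # (n_angles, n_cols)
    angles_deg: np.ndarray
    row_index: int
    pixel_size_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        a = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "angles_deg", a)
        if v.ndim != 2 or v.shape[0] != a.size:
            raise ValueError(f"values shape {v.shape} inconsistent with {a.size} angles")
        if a.size > 1 and np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")


@dataclass(frozen=True)
class Tomogram:
    """Reconstructed linear attenuation (1/cm) slices."""

    slices: np.ndarray  # (n_slices, ny, nx)
    voxel_size_mm: float
    energy_kev: float
    row_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.slices, dtype=float)
        object.__setattr__(self, "slices", s)
        if s.ndim != 3:
            raise ValueError("slices must be (n_slices, ny, nx)")
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite values in tomogram")


def repair_defunct_pixels(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace masked pixels by the median of their valid 3×3 neighbours.

    Pixels whose whole neighbourhood is masked are deferred and repaired in
    later sweeps, once neighbours have been filled.  Unmasked pixels are
    returned bit-identical.
    """
    img = np.array(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    if mask.all():
        raise ValueError("cannot repair a fully masked image")
    todo = np.argwhere(mask)
    remaining = mask.copy()
    while len(todo):
        progressed = []
        deferred = []
        for r, c in todo:
            r0, r1 = max(r - 1, 0), min(r + 2, img.shape[0])
            c0, c1 = max(c - 1, 0), min(c + 2, img.shape[1])
            neigh = ~remaining[r0:r1, c0:c1]
            neigh[r - r0, c - c0] = False
            if neigh.any():
                progressed.append((r, c, np.median(img[r0:r1, c0:c1][neigh])))
            else:
                deferred.append((r, c))
        if not progressed:  # cannot happen unless mask.all(), kept defensive
            raise ValueError("isolated masked region cannot be repaired")
        for r, c, v in progressed:
            img[r, c] = v
            remaining[r, c] = False
        todo = deferred
    return img


def average_flats(flats: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Mean of the before/after flat-field images."""
    stack = np.asarray(flats, dtype=float)
    return stack.reshape(-1, *stack.shape[-2:]).mean(axis=0)


def flat_field_correct(
    projection_counts: np.ndarray,
    flat_counts: np.ndarray,
    exposure_ratio: float = 1.0,
    count_floor: float = 0.5,
) -> np.ndarray:
    """µx = −ln(projection / (flat × exposure_ratio)).

    ``exposure_ratio`` is projection exposure / flat exposure.  Counts are
    floored at ``count_floor`` before the logarithm so that zero-count
    pixels (100 s at a low rate) stay finite; the bias is negligible at the
    default photon budget.  Flats should be defunct-repaired first.
    """
    proj = np.asarray(projection_counts, dtype=float)
    flat = np.asarray(flat_counts, dtype=float)
    if proj.shape != flat.shape:
        raise ValueError(f"projection {proj.shape} and flat {flat.shape} shapes differ")
    if not np.any(flat > 0):
        raise ValueError("flat field is all zero")
    denom = np.maximum(flat, count_floor) * exposure_ratio
    return -np.log(np.maximum(proj, count_floor) / denom)


def assemble_sinogram(
    mux_stack: np.ndarray, angles_deg: np.ndarray, row: int, pixel_size_mm: float
) -> Sinogram:
    """Extract the sinogram of one detector row from a (n_angles, n_rows,
    n_cols) µx stack."""
    return Sinogram(mux_stack[:, row, :], np.asarray(angles_deg, float), row, pixel_size_mm)


def correct_sinogram_background(
    sinogram: Sinogram,
    air_ranges: tuple[tuple[int, int], ...] = ((8, 44), (212, 248)),
    sample_threshold: float = 0.2,
) -> tuple[Sinogram, dict]:
    """Subtract a per-angle linear fit over the air columns.

    For every projection angle a straight line µx(col) is fitted by least
    squares over the columns in ``air_ranges`` (half-open, assumed outside
    the sample at every angle) and subtracted across the whole row; the air
    mean after correction is zero up to round-off.  Columns whose µx exceeds
    ``sample_threshold`` before the fit are flagged in the report as likely
    sample overlap — a warning, not an error.
    """
    cols = np.concatenate([np.arange(a, b) for a, b in air_ranges])
    if cols.size < 2:
        raise ValueError("air region must contain at least two columns")
    if cols.min() < 0 or cols.max() >= sinogram.values.shape[1]:
        raise ValueError("air columns outside the sinogram width")
    v = sinogram.values
    x = np.arange(v.shape[1], dtype=float)
    xa = x[cols]
    # per-angle least squares, vectorised over angles
    A = np.stack([xa, np.ones_like(xa)], axis=1)
    coef, *_ = np.linalg.lstsq(A, v[:, cols].T, rcond=None)  # (2, n_angles)
    fit = coef[0][:, None] * x[None, :] + coef[1][:, None]
    corrected = v - fit
    overlap = np.abs(v[:, cols]) > sample_threshold
    report = {
        "air_columns": cols,
        "n_overlap_flags": int(overlap.sum()),
        "overlap_warning": bool(overlap.any()),
        "air_mean_before": float(v[:, cols].mean()),
        "air_mean_after": float(corrected[:, cols].mean()),
        "fit_slope_mean": float(coef[0].mean()),
    }
    return replace(sinogram, values=corrected), report


def fbp_reconstruct(
    sinogram: Sinogram,
    filter_name: str = "ramp",
    center_offset_px: float = 0.0,
) -> np.ndarray:
    """Ramp-filtered back projection of one sinogram → µ slice in 1/cm.

    Uses frequency-domain filtering with power-of-two zero padding and
    linear interpolation during backprojection; ``filter_name`` may be any
    apodisation supported by scikit-image ("ramp", "cosine", "hann", ...).
    ``center_offset_px`` shifts the rotation axis from the default central
    column before reconstruction.
    """
    v = sinogram.values
    if v.ndim != 2:
        raise ValueError("sinogram values must be 2-D")
    if v.shape[0] < 2:
        raise ValueError("need at least 2 angles for reconstruction")
    if center_offset_px != 0.0:
        v = ndimage.shift(v, (0.0, -center_offset_px), order=1, mode="nearest")
    px_cm = 0.1 * sinogram.pixel_size_mm
    rec = iradon(
        v.T,
        theta=sinogram.angles_deg,
        filter_name=filter_name,
        interpolation="linear",
        circle=True,
        output_size=v.shape[1],
    )
    return rec / px_cm


def estimate_rotation_center(sinogram: Sinogram) -> float:
    """Rotation-axis offset (px) from opposing-view cross-correlation.

    Compares the mean 0–180° projection with the mirrored mean 180–360°
    projection; the optimum half-shift between them is the axis offset.
    Requires angles spanning both halves.
    """
    a = np.mod(sinogram.angles_deg, 360.0)
    first = sinogram.values[a < 180.0].mean(axis=0)
    second = sinogram.values[a >= 180.0]
    if second.size == 0:
        raise ValueError("angles do not cover 180-360 degrees")
    second = mirror_columns(second.mean(axis=0))
    first = first - first.mean()
    second = second - second.mean()
    cc = np.correlate(first, second, mode="full")
    k = int(np.argmax(cc))
    # parabolic sub-pixel refinement
    if 0 < k < cc.size - 1:
        y0, y1, y2 = cc[k - 1], cc[k], cc[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            k = k + 0.5 * (y0 - y2) / denom
    lag = k - (first.size - 1)
    return 0.5 * float(lag)


def half_sinogram_check(
    sinogram: Sinogram, filter_name: str = "ramp"
) -> dict:
    """Reconstruct [0°, 180°) and [180°, 360°) separately and compare.

    For an ideal parallel beam the two half-stacks are redundant (the
    second is the mirror of the first) and the discrepancy vanishes; beam
    divergence, axis drift or noise make it positive.  The second half is
    mapped onto [0°, 180°) by mirroring so both reconstructions share one
    geometry.  Returns the normalised RMS difference and both slices.
    """
    a = np.mod(sinogram.angles_deg, 360.0)
    sel1 = a < 180.0
    sel2 = ~sel1
    if not (sel1.any() and sel2.any()):
        raise ValueError("sinogram must span both halves of the 360 degree turn")
    s1 = Sinogram(
        sinogram.values[sel1], a[sel1], sinogram.row_index, sinogram.pixel_size_mm
    )
    order = np.argsort(a[sel2])
    s2 = Sinogram(
        mirror_columns(sinogram.values[sel2][order]),
        a[sel2][order] - 180.0,
        sinogram.row_index,
        sinogram.pixel_size_mm,
    )
    r1 = fbp_reconstruct(s1, filter_name=filter_name)
    r2 = fbp_reconstruct(s2, filter_name=filter_name)
    diff = r1 - r2
    mean = 0.5 * (r1 + r2)
    scale = float(np.sqrt(np.mean(mean**2)))
    rms = float(np.sqrt(np.mean(diff**2)))
    return {
        "rms_difference": rms,
        "normalized_rms": rms / scale if scale > 0 else 0.0,
        "slice_first_half": r1,
        "slice_second_half": r2,
    }
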