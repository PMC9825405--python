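"""Declarative run configuration: one file drives the whole pipeline.

Every stage (simulate → preprocess → reconstruct → decompose → metrology)
reads from a single :class:`RunConfig`; the effective configuration is
echoed into the output directory so a run is reproducible from its
artifacts alone.  All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .energy_calibration import SpectrometerGeometry
from .materials_spectra import EnergyGrid
from .phantom_sim import AcquisitionPlan, DetectorModel, PhantomConfig, _default_defunct

__all__ = ["RunConfig", "preset", "PRESETS"]


@dataclass(frozen=True)
class RunConfig:
    """Full description of one simulation + analysis run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    detector: DetectorModel = field(default_factory=DetectorModel)
    plan: AcquisitionPlan = field(default_factory=AcquisitionPlan)
    geometry: SpectrometerGeometry = field(default_factory=SpectrometerGeometry)
    mode: str = "parallel"  # "parallel" | "cone"
    expectation: bool = False  # noiseless expectation-mode acquisition
    spectra_csv: str | None = None  # None → built-in component spectra
    recon_rows: tuple[int, ...] | None = None  # None → 5 rows across the fill
    air_ranges: tuple[tuple[int, int], ...] | None = None  # None → scaled default
    filter_name: str = "ramp"
    count_floor: float = 0.5
    rois: dict | None = None  # None → derived from the phantom geometry
    esf_edge_box: tuple[int, int, int, int] | None = None
    output_dir: str = "spectoct_run"

    @property
    def seed(self) -> int:
        return self.plan.seed

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "phantom": dataclasses.asdict(self.phantom),
            "detector": {
                **{
                    k: v
                    for k, v in dataclasses.asdict(self.detector).items()
                    if k != "defunct_mask"
                },
                "defunct_pixels": [
                    [int(r), int(c)] for r, c in np.argwhere(self.detector.defunct_mask)
                ],
            },
            "plan": {
                "energies_kev": [float(e) for e in self.plan.energies.energies],
                "angles_deg": [float(a) for a in self.plan.angles_deg],
                "exposure_s": self.plan.exposure_s,
                "flat_exposure_s": self.plan.flat_exposure_s,
                "n_flats_before": self.plan.n_flats_before,
                "n_flats_after": self.plan.n_flats_after,
                "seed": self.plan.seed,
            },
            "geometry": dataclasses.asdict(self.geometry),
            "mode": self.mode,
            "expectation": self.expectation,
            "spectra_csv": self.spectra_csv,
            "recon_rows": None if self.recon_rows is None else list(self.recon_rows),
            "air_ranges": None
            if self.air_ranges is None
            else [list(r) for r in self.air_ranges],
            "filter_name": self.filter_name,
            "count_floor": self.count_floor,
            "rois": self.rois,
            "esf_edge_box": None if self.esf_edge_box is None else list(self.esf_edge_box),
            "output_dir": self.output_dir,
        }
        # YAML-friendly: tuples → lists
        d["phantom"] = _tuples_to_lists(d["phantom"])
        d["detector"] = _tuples_to_lists(d["detector"])
        d["geometry"] = _tuples_to_lists(d["geometry"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        ph = d.get("phantom", {})
        phantom = PhantomConfig(
            **{
                k: _listify(v)
                for k, v in ph.items()
            }
        )
        det = dict(d.get("detector", {}))
        defunct_pairs = det.pop("defunct_pixels", None)
        if defunct_pairs is None:
            mask = _default_defunct(det.get("n_rows", 256), det.get("n_cols", 256))
        else:
            mask = np.zeros((det.get("n_rows", 256), det.get("n_cols", 256)), dtype=bool)
            for r, c in defunct_pairs:
                mask[r, c] = True
        detector = DetectorModel(
            **{k: _listify(v) for k, v in det.items()}, defunct_mask=mask
        )
        pl = dict(d.get("plan", {}))
        plan = AcquisitionPlan(
            energies=EnergyGrid(np.asarray(pl.get("energies_kev", [12.645, 12.658, 12.662, 12.685]))),
            angles_deg=np.asarray(pl.get("angles_deg", np.arange(0.0, 360.0, 1.8))),
            exposure_s=pl.get("exposure_s", 100.0),
            flat_exposure_s=pl.get("flat_exposure_s", 1000.0),
            n_flats_before=pl.get("n_flats_before", 2),
            n_flats_after=pl.get("n_flats_after", 2),
            seed=pl.get("seed", 0),
        )
        geometry = SpectrometerGeometry(
            **{k: _listify(v) for k, v in d.get("geometry", {}).items()}
        )
        return cls(
            phantom=phantom,
            detector=detector,
            plan=plan,
            geometry=geometry,
            mode=d.get("mode", "parallel"),
            expectation=d.get("expectation", False),
            spectra_csv=d.get("spectra_csv"),
            recon_rows=None if d.get("recon_rows") is None else tuple(d["recon_rows"]),
            air_ranges=None
            if d.get("air_ranges") is None
            else tuple(tuple(r) for r in d["air_ranges"]),
            filter_name=d.get("filter_name", "ramp"),
            count_floor=d.get("count_floor", 0.5),
            rois=d.get("rois"),
            esf_edge_box=None
            if d.get("esf_edge_box") is None
            else tuple(d["esf_edge_box"]),
            output_dir=d.get("output_dir", "spectoct_run"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_tuples_to_lists(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _listify(v):
    if isinstance(v, list):
        return tuple(_listify(x) for x in v)
    return v


def _smoke() -> RunConfig:
    """Tiny end-to-end configuration (64×64 detector, 40 angles, 2 energies)."""
    n = 64
    vox = 0.212  # mm; 4× coarser than the full grid, same field of view
    return RunConfig(
        phantom=PhantomConfig(voxel_size_mm=vox, shape=(n, n, n)),
        detector=DetectorModel(
            n_rows=n,
            n_cols=n,
            effective_pixel_um=vox * 1000,
            pixel_pitch_um=vox * 1000 * 55.0 / 53.0,
            gap_columns=(15, 45),
            defunct_mask=_default_defunct(n, n),
            psf_sigma_um=0.0,
        ),
        plan=AcquisitionPlan(angles_deg=np.arange(0.0, 360.0, 9.0)),
        recon_rows=(26, 30, 34),
        output_dir="spectoct_smoke",
    )


def _full_scale() -> RunConfig:
    """Full-scale protocol: 256×256 detector, 4 energies, 200 angles, 100 s."""
    return RunConfig(output_dir="spectoct_full_scale")


def _cone_demo() -> RunConfig:
    """Smoke-sized run with the fan-beam magnification approximation on."""
    cfg = _smoke()
    return cfg.replace(mode="cone", expectation=True, output_dir="spectoct_cone_demo")


PRESETS = {"smoke": _smoke, "full-scale": _full_scale, "cone-demo": _cone_demo}


def preset(name: str) -> RunConfig:
    """One of the canned configurations: ``smoke``, ``full-scale``,
    ``cone-demo``."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
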