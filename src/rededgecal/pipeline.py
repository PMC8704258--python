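"""Mission-level orchestration shared by the library and the CLI.

Ties the stages together in the operational order: load a mission
directory, extract the mission panel radiance, convert survey captures to
panel-referenced (uncorrected) reflectance, compute and apply the DLS
correction factors, and emit a machine-readable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .bands import BAND_NAMES, get_band
from .capture import Capture, PanelSpec, ReflectanceRaster, read_capture_dir
from .correction import (
    DEFAULT_MODELS,
    CorrectionFactor,
    RegressionModel,
    correct_reflectance,
    fit_crp_dls,
    mission_factors,
)
from .panels import collect_samples
from .radiometry import crp_reflectance, dn_to_radiance


@dataclass
class Mission:
    """A mission directory loaded into memory."""

    calib: list[Capture]
    survey: list[Capture]
    panel: PanelSpec
    manifest: dict


def load_mission(mission_dir: str | Path) -> Mission:
    """Load a mission directory written by the simulator or laid out alike."""
    mission_dir = Path(mission_dir)
    manifest_path = mission_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {mission_dir}")
    manifest = json.loads(manifest_path.read_text())
    p = manifest["panel"]
    panel = PanelSpec(
        panel_id=p["panel_id"], reflectance=p["reflectance"], aoi=tuple(p["aoi"])
    )
    calib: list[Capture] = []
    survey: list[Capture] = []
    for name in manifest["captures"]:
        cap = read_capture_dir(mission_dir / name)
        (calib if cap.role == "calibration" else survey).append(cap)
    return Mission(calib=calib, survey=survey, panel=panel, manifest=manifest)


def capture_to_reflectance(
    capture: Capture, l_crp: dict[str, float], nodata: float = -9999.0
) -> ReflectanceRaster:
    """Panel-referenced reflectance of one capture (DN → radiance → Eq-3 ratio)."""
    h, w = capture.shape
    out = np.empty((len(BAND_NAMES), h, w), dtype=np.float32)
    for i, name in enumerate(BAND_NAMES):
        band = get_band(name)
        rad = dn_to_radiance(capture.planes[name], capture.tags[name], band)
        out[i] = crp_reflectance(rad, l_crp[name], band).astype(np.float32)
    return ReflectanceRaster(bands=out, nodata=nodata)


def refit_models(mission: Mission) -> dict[str, RegressionModel]:
    """Refit the CRP–DLS regression from this mission's calibration shots."""
    samples = collect_samples(mission.calib, mission.panel)
    return {b: fit_crp_dls(samples[b], b) for b in BAND_NAMES}


def calibrate_mission(
    mission: Mission,
    models: dict[str, RegressionModel] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, CorrectionFactor], dict]:
    """Panel extraction + Eq-8 factors; report includes versions for reproducibility."""
    factors, report = mission_factors(mission.calib, mission.panel,
                                      models or DEFAULT_MODELS)
    report["package_version"] = __version__
    report["n_calibration_captures"] = len(mission.calib)
    if seed is not None:
        report["seed"] = seed
    return factors, report


def correct_mission_raster(
    raster: ReflectanceRaster, factors: dict[str, CorrectionFactor]
) -> ReflectanceRaster:
    return correct_reflectance(raster, factors)
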