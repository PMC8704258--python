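"""Forward capture simulator: scenes, irradiance scenarios, and synthetic missions.

The simulator inverts the sensor model so that every pipeline stage can be
verified against known truth. The physical story:

* The sky delivers irradiance ``E_sky(band, t)`` (W/m²/nm). The DLS, facing
  open sky, records exactly ``E_sky``.
* The ground-level reflectance panel additionally receives path-scattered
  light, so the irradiance reaching it is ``E_panel = a_true*E_sky + b_true``
  per band — the linear cross-sensor offset the correction model estimates.
* Surfaces are Lambertian: radiance ``L = E * rho / pi``.
* Raw counts invert the radiometric model:
  ``DN = DNBL + 65536 * L * (te + a2*y - a3*te*y) * g / (a1 * V(x, y))``
  plus optional Gaussian read noise, rounded and clipped to 16 bits.

With this construction the panel-only reflectance is biased low by
``E_sky / E_panel`` and the DLS-regression correction recovers the true
reflectance exactly in the noise-free limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .bands import BAND_NAMES, get_band
from .capture import (
    DN_MAX,
    DN_SCALE,
    Capture,
    PanelSpec,
    RadiometricTags,
    ReflectanceRaster,
    write_capture,
    write_raster,
)
from .radiometry import row_denominator, vignette_map

# Spectral shape of downwelling irradiance relative to the blue band: both
# sensors record a decreasing trend from visible to NIR.
IRRADIANCE_SHAPE = {"blue": 1.0, "green": 0.95, "red": 0.85, "rededge": 0.80, "nir": 0.70}

# Per-band ground-truth sensor offsets (a_true, b_true) default to the
# packaged regression coefficients so simulated missions exercise realistic
# correction magnitudes.
DEFAULT_SENSOR_OFFSET = {
    "blue": (1.0118, 0.0036),
    "green": (1.1290, 0.0073),
    "red": (1.0875, 0.0210),
    "rededge": (1.0674, 0.0015),
    "nir": (1.2506, 0.0155),
}


@dataclass(frozen=True)
class Scenario:
    """Irradiance conditions and sensor offsets for one simulated mission.

    ``irradiance_profile(t)`` returns the blue-band sky irradiance
    (W/m²/nm) at mission fraction ``t`` in [0, 1]; other bands follow the
    fixed spectral shape. Presets: ``sunny`` holds near the 1.8 peak,
    ``cloudy`` near 0.5 — the span observed between overcast and clear
    conditions.
    """

    name: str = "sunny"
    irradiance_profile: Callable[[float], float] | None = None
    sensor_offset: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SENSOR_OFFSET)
    )
    noise_dn: float = 20.0  # Gaussian read-noise sigma in raw counts
    nir_path_radiance: float = 0.0  # optional additive NIR scattering excess
    seed: int = 0

    def sky_irradiance(self, band: str, t: float) -> float:
        if self.irradiance_profile is not None:
            level = self.irradiance_profile(t)
        elif self.name == "sunny":
            level = 1.7 + 0.1 * t  # thin-cloud drift around the 1.8 peak
        elif self.name == "cloudy":
            level = 0.45 + 0.1 * t
        else:
            raise ValueError(f"no irradiance profile for scenario {self.name!r}")
        e = level * IRRADIANCE_SHAPE[band]
        if e <= 0:
            raise ValueError("irradiance must be positive")
        return e

    def panel_irradiance_truth(self, band: str, t: float) -> float:
        a, b = self.sensor_offset[band]
        return a * self.sky_irradiance(band, t) + b


def sunny_scenario(seed: int = 0, **kw) -> Scenario:
    return Scenario(name="sunny", seed=seed, **kw)


def cloudy_scenario(seed: int = 0, **kw) -> Scenario:
    return Scenario(name="cloudy", seed=seed, **kw)


# Per-class 5-band reflectance spectra (blue, green, red, rededge, nir).
# Vegetation classes satisfy nir > rededge > green > red (chlorophyll
# absorption in red, strong NIR plateau).
CLASS_SPECTRA: dict[str, dict[str, float]] = {
    "marsh": {"blue": 0.04, "green": 0.08, "red": 0.06, "rededge": 0.18, "nir": 0.30},
    "grass": {"blue": 0.04, "green": 0.09, "red": 0.05, "rededge": 0.28, "nir": 0.50},
    "forest": {"blue": 0.03, "green": 0.07, "red": 0.04, "rededge": 0.26, "nir": 0.55},
    "soil": {"blue": 0.12, "green": 0.16, "red": 0.20, "rededge": 0.23, "nir": 0.28},
    "water": {"blue": 0.06, "green": 0.05, "red": 0.03, "rededge": 0.02, "nir": 0.01},
    "concrete": {"blue": 0.25, "green": 0.28, "red": 0.30, "rededge": 0.31, "nir": 0.32},
}
VEGETATION_CLASSES = ("marsh", "grass", "forest")


@dataclass
class SceneMap:
    """A class-labelled scene: integer class raster + per-class spectra."""

    class_raster: np.ndarray  # int codes indexing class_names
    class_names: tuple[str, ...]
    spectra: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CLASS_SPECTRA.items()}
    )

    def __post_init__(self) -> None:
        for name in self.class_names:
            s = self.spectra[name]
            if not all(0.0 < s[b] < 1.0 for b in BAND_NAMES):
                raise ValueError(f"class {name!r} spectrum must lie in (0, 1)")
            if name in VEGETATION_CLASSES and not (
                s["nir"] > s["rededge"] > s["green"] > s["red"]
            ):
                raise ValueError(f"vegetation class {name!r} violates nir>rededge>green>red")

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_raster.shape

    def reflectance_truth(self, nodata: float = -9999.0) -> ReflectanceRaster:
        h, w = self.shape
        out = np.empty((len(BAND_NAMES), h, w), dtype=np.float32)
        for i, band in enumerate(BAND_NAMES):
            lut = np.array([self.spectra[n][band] for n in self.class_names])
            out[i] = lut[self.class_raster]
        return ReflectanceRaster(bands=out, nodata=nodata)

    def class_mask(self, names: tuple[str, ...]) -> np.ndarray:
        codes = [self.class_names.index(n) for n in names if n in self.class_names]
        return np.isin(self.class_raster, codes)


def default_scene(width: int = 160, height: int = 120) -> SceneMap:
    """A mixed scene: vertical strips of the six surface classes."""
    names = tuple(CLASS_SPECTRA)
    raster = np.zeros((height, width), dtype=np.intp)
    edges = np.linspace(0, width, len(names) + 1).astype(int)
    for i in range(len(names)):
        raster[:, edges[i]:edges[i + 1]] = i
    return SceneMap(class_raster=raster, class_names=names)


def default_panel_spec(width: int = 160, height: int = 120) -> PanelSpec:
    """CRP panel AOI centred in the calibration frame (~1/5 of each side)."""
    ph, pw = max(12, height // 5), max(12, width // 5)
    r0, c0 = (height - ph) // 2, (width - pw) // 2
    return PanelSpec(
        panel_id="crp",
        reflectance={b: get_band(b).crp_reflectance for b in BAND_NAMES},
        aoi=(r0, c0, r0 + ph, c0 + pw),
    )


def default_tags(width: int, height: int, band: str) -> RadiometricTags:
    """Plausible RedEdge-M-like tags; exposure varies slightly per band."""
    i = BAND_NAMES.index(band)
    return RadiometricTags(
        a1=6.0e-4,
        a2=1.0e-7,
        a3=1.0e-5,
        te=1.0e-3 * (1.0 + 0.05 * i),
        g=1.0,
        dn_black_level=4800.0,
        vignette_center=((width - 1) / 2.0, (height - 1) / 2.0),
        vignette_coeffs=(1.0e-4, 1.0e-7, 0.0, 0.0, 0.0, 0.0),
    )


def radiance_to_dn(
    radiance: np.ndarray,
    tags: RadiometricTags,
    rng: np.random.Generator | None = None,
    noise_dn: float = 0.0,
    quantize: bool = True,
) -> np.ndarray:
    """Invert the radiometric model: radiance field → raw counts.

    With ``quantize=True`` (the camera's storage format) counts are rounded
    and clipped to uint16, which bounds any later radiance recovery at the
    half-count level. ``quantize=False`` returns continuous float counts,
    exposing the exact algebraic inverse of the DN→radiance model for
    round-trip verification.
    """
    h, w = radiance.shape
    v = vignette_map(w, h, tags)
    denom = row_denominator(tags, h)[:, None]
    dn = tags.dn_black_level + DN_SCALE * radiance * denom * tags.g / (tags.a1 * v)
    if noise_dn > 0:
        if rng is None:
            raise ValueError("rng required when noise_dn > 0")
        dn = dn + rng.normal(0.0, noise_dn, size=dn.shape)
    if not quantize:
        return dn
    return np.clip(np.rint(dn), 0, DN_MAX).astype(np.uint16)


def simulate_capture(
    scene: SceneMap,
    scenario: Scenario,
    t: float = 0.0,
    role: str = "survey",
    panel: PanelSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Capture, dict]:
    """Simulate one capture at mission fraction ``t``.

    Calibration captures embed the CRP panel (at its manufacturer
    reflectance) over the panel AOI, illuminated with the path-scattering
    excess; everything else sees the sky irradiance. Returns the capture
    and a truth dict with the reflectance raster, per-band radiance fields,
    sky/panel irradiance, and a per-band saturation count.
    """
    h, w = scene.shape
    if rng is None:
        rng = np.random.default_rng([scenario.seed, int(round(t * 1e6)),
                                     0 if role == "calibration" else 1])
    if role == "calibration" and panel is None:
        panel = default_panel_spec(w, h)
    truth_reflectance = scene.reflectance_truth()
    planes: dict[str, np.ndarray] = {}
    tags: dict[str, RadiometricTags] = {}
    dls: dict[str, float] = {}
    truth: dict = {
        "reflectance": truth_reflectance,
        "radiance": {},
        "sky_irradiance": {},
        "panel_irradiance": {},
        "saturated": {},
        "t": t,
    }
    for band in BAND_NAMES:
        e_sky = scenario.sky_irradiance(band, t)
        rho = truth_reflectance.band(band).astype(np.float64)
        radiance = e_sky * rho / np.pi
        if band == "nir" and scenario.nir_path_radiance:
            radiance = radiance + scenario.nir_path_radiance
        if role == "calibration":
            e_panel = scenario.panel_irradiance_truth(band, t)
            r0, c0, r1, c1 = panel.aoi
            radiance[r0:r1, c0:c1] = e_panel * panel.reflectance[band] / np.pi
            truth["panel_irradiance"][band] = e_panel
        band_tags = default_tags(w, h, band)
        dn = radiance_to_dn(radiance, band_tags, rng=rng, noise_dn=scenario.noise_dn)
        planes[band] = dn
        tags[band] = band_tags
        dls[band] = e_sky
        truth["radiance"][band] = radiance
        truth["sky_irradiance"][band] = e_sky
        truth["saturated"][band] = int((dn >= DN_MAX).sum())
    capture = Capture(
        planes=planes, tags=tags, dls_irradiance=dls,
        timestamp=f"t={t:.4f}", role=role,
    )
    return capture, truth


def simulate_mission(
    scene: SceneMap,
    scenario: Scenario,
    n_calib: int = 2,
    n_survey: int = 4,
    out_dir: str | Path | None = None,
    panel: PanelSpec | None = None,
) -> dict:
    """Simulate a full mission: calibration shots bracketing survey shots.

    Calibration captures sit at the mission start and end; survey captures
    are spread uniformly in between. If ``out_dir`` is given, writes a
    directory tree consumable by the CLI (captures + sidecars + truth
    reflectance TIFF + manifest) and records file paths in the manifest.
    Returns a dict with captures, truths, the panel spec and the manifest.
    """
    if n_calib < 1:
        raise ValueError("a mission needs at least one calibration capture")
    h, w = scene.shape
    panel = panel or default_panel_spec(w, h)
    calib_times = [0.0] if n_calib == 1 else list(np.linspace(0.0, 1.0, n_calib))
    survey_times = list(np.linspace(0.1, 0.9, n_survey)) if n_survey else []
    captures: list[tuple[str, Capture, dict]] = []
    for i, t in enumerate(calib_times):
        cap, truth = simulate_capture(scene, scenario, t, "calibration", panel=panel)
        captures.append((f"calib_{i:03d}", cap, truth))
    for i, t in enumerate(survey_times):
        cap, truth = simulate_capture(scene, scenario, t, "survey", panel=panel)
        captures.append((f"survey_{i:03d}", cap, truth))
    manifest = {
        "scenario": {
            "name": scenario.name,
            "noise_dn": scenario.noise_dn,
            "seed": scenario.seed,
            "sensor_offset": {b: list(v) for b, v in scenario.sensor_offset.items()},
        },
        "panel": {"panel_id": panel.panel_id, "aoi": list(panel.aoi),
                  "reflectance": dict(panel.reflectance)},
        "n_calib": n_calib,
        "n_survey": n_survey,
        "captures": [name for name, _, _ in captures],
    }
    result = {
        "captures": {name: cap for name, cap, _ in captures},
        "truths": {name: truth for name, _, truth in captures},
        "panel": panel,
        "manifest": manifest,
        "truth_reflectance": scene.reflectance_truth(),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, cap, _ in captures:
            write_capture(cap, out_dir / name)
        truth_dir = out_dir / "truth"
        truth_dir.mkdir(exist_ok=True)
        write_raster(result["truth_reflectance"], truth_dir / "reflectance.tif")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
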