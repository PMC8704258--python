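"""Panel radiance extraction and CRP/DLS irradiance bookkeeping.

One calibration capture yields, per band, a pair of comparable irradiance
values: the panel-derived irradiance ``Irr_CRP = pi * L_CRP / rho_CRP``
(Lambertian panel of known reflectance) and the irradiance recorded by the
Downwelling Light Sensor. These pairs feed the cross-sensor regression in
:mod:`rededgecal.correction`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .bands import BAND_NAMES, BandDefinition, get_band
from .capture import Capture, PanelSpec
from .radiometry import dn_to_radiance

logger = logging.getLogger(__name__)

# DN at or above 0.996 of full scale is treated as clipped.
SATURATION_DN = 65280


class CalibrationError(ValueError):
    """A calibration capture is unusable (saturated panel, bad AOI, ...)."""


@dataclass(frozen=True)
class PanelStats:
    """QA statistics for one panel-AOI extraction."""

    mean_radiance: float
    std_radiance: float
    n_pixels: int
    saturated_fraction: float
    n_clamped: int


@dataclass(frozen=True)
class CalibrationSample:
    """One calibration capture's per-band irradiance pair."""

    band: BandDefinition
    irr_crp: float   # panel-derived irradiance (W/m²/nm)
    irr_dls: float   # DLS-recorded irradiance (W/m²/nm)
    l_crp: float     # panel mean radiance (W/m²/sr/nm)
    timestamp: str = ""
    weather_label: str = "unknown"


def shrink_aoi(aoi: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    """Central 50 %-area sub-rectangle of a half-open (r0, c0, r1, c1) AOI.

    Each side is scaled by sqrt(0.5) to avoid edge contamination from the
    white backing paper around real panels.
    """
    r0, c0, r1, c1 = aoi
    scale = math.sqrt(0.5)
    h, w = r1 - r0, c1 - c0
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    nr0 = r0 + (h - nh) // 2
    nc0 = c0 + (w - nw) // 2
    return (nr0, nc0, nr0 + nh, nc0 + nw)


def extract_panel_radiance(
    capture: Capture,
    spec: PanelSpec,
    band: str | BandDefinition,
    *,
    shrink: bool = True,
) -> tuple[float, PanelStats]:
    """Mean panel radiance over the unsaturated AOI pixels of one band.

    The AOI is shrunk to its central 50 % area before averaging (white-paper
    edge guard). Saturated pixels (DN >= 65280) are excluded; if more than
    half the AOI is saturated the shot is rejected as unusable.
    """
    band = get_band(band) if isinstance(band, str) else band
    h, w = capture.shape
    aoi = shrink_aoi(spec.aoi) if shrink else spec.aoi
    r0, c0, r1, c1 = aoi
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise CalibrationError(f"panel AOI {aoi} outside image bounds {h}x{w}")
    dn = capture.planes[band.name][r0:r1, c0:c1]
    saturated = dn >= SATURATION_DN
    sat_frac = float(saturated.mean())
    if sat_frac > 0.5:
        raise CalibrationError(
            f"{band.name}: {sat_frac:.0%} of panel AOI saturated; "
            "calibration shot unusable"
        )
    radiance = dn_to_radiance(capture.planes[band.name], capture.tags[band.name], band)
    vals = radiance.values[r0:r1, c0:c1][~saturated]
    stats = PanelStats(
        mean_radiance=float(vals.mean()),
        std_radiance=float(vals.std()),
        n_pixels=int(vals.size),
        saturated_fraction=sat_frac,
        n_clamped=radiance.n_clamped,
    )
    return stats.mean_radiance, stats


def panel_irradiance(l_crp: float, band: str | BandDefinition) -> float:
    """Incident irradiance implied by the panel radiance: ``pi * L / rho``."""
    band = get_band(band) if isinstance(band, str) else band
    if l_crp < 0:
        raise ValueError("panel radiance must be non-negative")
    return math.pi * l_crp / band.crp_reflectance


def dls_radiance(irr_dls: float) -> float:
    """Equivalent radiance of the DLS irradiance reading: ``Irr / pi``."""
    if irr_dls < 0:
        raise ValueError("DLS irradiance must be non-negative")
    return irr_dls / math.pi


def collect_samples(
    captures: list[Capture],
    spec: PanelSpec,
    *,
    weather_label: str = "unknown",
    dls_premultiplier: Mapping[str, float] | None = None,
) -> dict[str, list[CalibrationSample]]:
    """Build per-band calibration samples from a mission's calibration shots.

    Survey-role captures are skipped with a log notice. Each usable
    calibration capture contributes one sample per band (pre- and
    post-flight shots are both retained). ``dls_premultiplier`` is a
    per-band scale hook on the DLS reading, reserved for sun-angle
    (Fresnel) diffuser compensation; the default is the identity.
    """
    samples: dict[str, list[CalibrationSample]] = {b: [] for b in BAND_NAMES}
    n_used = 0
    for cap in captures:
        if cap.role != "calibration":
            logger.info("skipping %s capture at %s", cap.role, cap.timestamp)
            continue
        for name in BAND_NAMES:
            band = get_band(name)
            l_crp, _stats = extract_panel_radiance(cap, spec, band)
            samples[name].append(
                CalibrationSample(
                    band=band,
                    irr_crp=panel_irradiance(l_crp, band),
                    irr_dls=cap.dls_irradiance[name]
                    * (dls_premultiplier.get(name, 1.0) if dls_premultiplier else 1.0),
                    l_crp=l_crp,
                    timestamp=cap.timestamp,
                    weather_label=weather_label,
                )
            )
        n_used += 1
    if n_used == 0:
        raise CalibrationError("no usable calibration captures")
    return samples
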