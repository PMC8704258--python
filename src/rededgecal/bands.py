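"""Spectral band constants for the RedEdge-M camera and its calibration panels.

The camera records five narrow bands in the visible/near-infrared region.
Each band ships with the manufacturer-characterised reflectance of the
Calibrated Reflectance Panel (CRP), the ~49 % diffuse panel photographed on
the ground before and after every flight. The MAPIR four-panel board
reflectances are included as validation constants only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BAND_NAMES = ("blue", "green", "red", "rededge", "nir")


@dataclass(frozen=True)
class BandDefinition:
    """One spectral band: centre/width in nm and the CRP panel reflectance.

    ``range_nm`` is the closed interval ``[centre - width/2, centre + width/2]``,
    derived rather than stored independently so the invariant cannot drift.
    """

    name: str
    center_nm: float
    bandwidth_nm: float
    crp_reflectance: float
    range_nm: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.name not in BAND_NAMES:
            raise ValueError(f"unknown band name {self.name!r}; expected one of {BAND_NAMES}")
        if not 0.0 < self.crp_reflectance < 1.0:
            raise ValueError("crp_reflectance must be a fraction in (0, 1)")
        half = self.bandwidth_nm / 2.0
        object.__setattr__(
            self, "range_nm", (self.center_nm - half, self.center_nm + half)
        )


# Manufacturer band table: centre (nm), width (nm), CRP reflectance.
REDEDGE_M_BANDS: dict[str, BandDefinition] = {
    "blue": BandDefinition("blue", 475.0, 20.0, 0.4893),
    "green": BandDefinition("green", 560.0, 20.0, 0.4895),
    "red": BandDefinition("red", 668.0, 10.0, 0.4899),
    "rededge": BandDefinition("rededge", 717.0, 10.0, 0.4901),
    "nir": BandDefinition("nir", 840.0, 40.0, 0.4905),
}

# MAPIR four-panel board reflectances per band (black, dark gray, light gray,
# white). Used only as fixtures when validating panel extraction.
MAPIR_REFLECTANCE: dict[str, dict[str, float]] = {
    "black": {"blue": 0.0198, "green": 0.0196, "red": 0.0192, "rededge": 0.0194, "nir": 0.0202},
    "dark_gray": {"blue": 0.1880, "green": 0.1974, "red": 0.1935, "rededge": 0.2151, "nir": 0.2334},
    "light_gray": {"blue": 0.2561, "green": 0.2666, "red": 0.2652, "rededge": 0.2670, "nir": 0.2797},
    "white": {"blue": 0.8269, "green": 0.8722, "red": 0.8772, "rededge": 0.8762, "nir": 0.8668},
}


def get_band(name: str) -> BandDefinition:
    try:
        return REDEDGE_M_BANDS[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; expected one of {BAND_NAMES}") from None
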