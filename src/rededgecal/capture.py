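"""Domain types and file I/O for raw multispectral captures and reflectance rasters.

A *capture* is one camera shot: five single-band 16-bit TIFF planes plus a
JSON sidecar holding the radiometric metadata the camera would write to
EXIF/XMP tags (calibration coefficients, exposure, gain, black level,
vignette polynomial, DLS irradiance). The sidecar is the canonical,
versioned metadata carrier; it keeps fixtures bit-exact and testable.

Conventions used throughout the package: 0-based ``(row, col)`` pixel
coordinates, rectangles half-open, raw counts normalised by 65536.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .bands import BAND_NAMES

SIDECAR_SCHEMA_VERSION = "1.0"
DN_SCALE = 65536  # raw counts are normalised to [0, 1] by this constant
DN_MAX = 65535
BAND_ORDER: tuple[str, ...] = BAND_NAMES  # fixed (blue, green, red, rededge, nir)


class SchemaError(ValueError):
    """Sidecar or raster metadata violates the published schema."""


class RadiometricTags(BaseModel):
    """Per-band radiometric metadata of one capture.

    ``a1, a2, a3`` are the sensor's radiometric calibration coefficients,
    ``te`` the exposure time in seconds, ``g`` the gain, ``dn_black_level``
    the dark offset in raw counts. ``vignette_center`` is ``(cx, cy)`` in
    pixel (col, row) coordinates and ``vignette_coeffs`` the six radial
    polynomial coefficients ``k0..k5``.
    """

    model_config = ConfigDict(frozen=True)

    a1: float
    a2: float = 0.0
    a3: float = 0.0
    te: float = Field(gt=0, description="exposure time (s)")
    g: float = Field(gt=0, description="sensor gain")
    dn_black_level: float = Field(ge=0, lt=DN_SCALE, description="black level (raw counts)")
    vignette_center: tuple[float, float]
    vignette_coeffs: tuple[float, float, float, float, float, float]
    dn_scale: int = DN_SCALE

    @model_validator(mode="after")
    def _finite(self) -> "RadiometricTags":
        vals = [self.a1, self.a2, self.a3, self.te, self.g, self.dn_black_level,
                *self.vignette_center, *self.vignette_coeffs]
        if not np.all(np.isfinite(vals)):
            raise ValueError("radiometric tags must be finite")
        return self


class CaptureSidecar(BaseModel):
    """Versioned JSON sidecar: per-band tags + per-band DLS irradiance."""

    model_config = ConfigDict(frozen=True)

    schema_version: str = SIDECAR_SCHEMA_VERSION
    role: str  # "calibration" | "survey"
    timestamp: str
    tags: dict[str, RadiometricTags]
    dls_irradiance: dict[str, float]

    @model_validator(mode="after")
    def _complete(self) -> "CaptureSidecar":
        if self.role not in ("calibration", "survey"):
            raise ValueError(f"role must be 'calibration' or 'survey', got {self.role!r}")
        for group, d in (("tags", self.tags), ("dls_irradiance", self.dls_irradiance)):
            missing = [b for b in BAND_NAMES if b not in d]
            if missing:
                raise ValueError(f"{group} missing bands: {missing}")
        for band, irr in self.dls_irradiance.items():
            if irr < 0:
                raise ValueError(f"dls_irradiance.{band} must be >= 0")
        return self


@dataclass
class Capture:
    """One camera shot: per-band raw DN planes plus radiometric metadata."""

    planes: dict[str, np.ndarray]  # uint16, identical (rows, cols) per band
    tags: dict[str, RadiometricTags]
    dls_irradiance: dict[str, float]
    timestamp: str = "1970-01-01T00:00:00Z"
    role: str = "survey"

    def __post_init__(self) -> None:
        missing = [b for b in BAND_NAMES if b not in self.planes]
        if missing:
            raise SchemaError(f"capture missing band planes: {missing}")
        shapes = {b: p.shape for b, p in self.planes.items()}
        if len(set(shapes.values())) != 1:
            raise SchemaError(f"band planes differ in shape: {shapes}")
        for b, p in self.planes.items():
            if p.dtype != np.uint16:
                raise SchemaError(f"plane {b!r} must be uint16, got {p.dtype}")
        h, w = self.shape
        for b in BAND_NAMES:
            cx, cy = self.tags[b].vignette_center
            if not (0 <= cx < w and 0 <= cy < h):
                raise SchemaError(
                    f"{b}.vignette_center ({cx}, {cy}) outside image bounds {w}x{h}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def sidecar(self) -> CaptureSidecar:
        return CaptureSidecar(
            role=self.role,
            timestamp=self.timestamp,
            tags=self.tags,
            dls_irradiance=self.dls_irradiance,
        )


@dataclass(frozen=True)
class PanelSpec:
    """A reflectance panel and its area of interest on the calibration image.

    The AOI is an axis-aligned rectangle in 0-based pixel coordinates,
    half-open: ``(row0, col0, row1, col1)`` covering rows ``row0..row1-1``.
    """

    panel_id: str
    reflectance: Mapping[str, float]
    aoi: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.aoi
        if (r1 - r0) * (c1 - c0) < 100:
            raise ValueError("panel AOI must cover at least 100 pixels")
        for band in BAND_NAMES:
            rho = self.reflectance.get(band)
            if rho is None:
                raise ValueError(f"panel reflectance missing band {band!r}")
            if not 0.0 < rho < 1.0:
                raise ValueError(f"panel reflectance for {band!r} must be in (0, 1)")


@dataclass
class ReflectanceRaster:
    """Multiband reflectance image: (band, row, col) float32, fixed band order."""

    bands: np.ndarray
    band_order: tuple[str, ...] = BAND_ORDER
    nodata: float = -9999.0
    geo: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float32)
        if self.bands.ndim != 3 or self.bands.shape[0] != len(self.band_order):
            raise SchemaError(
                f"expected ({len(self.band_order)}, rows, cols) array, got {self.bands.shape}"
            )
        if tuple(self.band_order) != BAND_ORDER:
            raise SchemaError(f"band_order must be {BAND_ORDER}, got {self.band_order}")

    def band(self, name: str) -> np.ndarray:
        return self.bands[self.band_order.index(name)]

    def valid_mask(self) -> np.ndarray:
        """True where no band is nodata."""
        return ~np.any(self.bands == self.nodata, axis=0)


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def read_sidecar(path: str | Path) -> CaptureSidecar:
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return CaptureSidecar.model_validate(raw)
    except ValidationError as exc:
        raise SchemaError(
            f"invalid sidecar {path}: {_format_validation_error(exc)}"
        ) from exc


def read_capture(image_paths: Mapping[str, str | Path], sidecar_path: str | Path) -> Capture:
    """Read one capture from five single-band uint16 TIFFs and a JSON sidecar."""
    sidecar = read_sidecar(sidecar_path)
    missing = [b for b in BAND_NAMES if b not in image_paths]
    if missing:
        raise SchemaError(f"image_paths missing bands: {missing}")
    planes: dict[str, np.ndarray] = {}
    for band in BAND_NAMES:
        arr = tifffile.imread(image_paths[band])
        if arr.ndim != 2 or arr.dtype != np.uint16:
            raise SchemaError(
                f"{image_paths[band]}: expected single-band uint16 TIFF, "
                f"got shape {arr.shape} dtype {arr.dtype}"
            )
        planes[band] = arr
    return Capture(
        planes=planes,
        tags=dict(sidecar.tags),
        dls_irradiance=dict(sidecar.dls_irradiance),
        timestamp=sidecar.timestamp,
        role=sidecar.role,
    )


def write_capture(capture: Capture, directory: str | Path) -> dict[str, Path]:
    """Write a capture as lossless per-band uint16 TIFFs plus ``sidecar.json``.

    Returns the file map; ``read_capture`` on it is the bitwise identity.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        files: dict[str, Path] = {}
        for band in BAND_NAMES:
            p = directory / f"{band}.tif"
            tifffile.imwrite(p, capture.planes[band])
            files[band] = p
        sidecar_path = directory / "sidecar.json"
        sidecar_path.write_text(capture.sidecar().model_dump_json(indent=2))
        files["sidecar"] = sidecar_path
    except OSError as exc:
        raise OSError(f"failed writing capture to {directory}: {exc}") from exc
    return files


def read_capture_dir(directory: str | Path) -> Capture:
    """Read a capture laid out as ``<band>.tif`` files plus ``sidecar.json``."""
    directory = Path(directory)
    return read_capture(
        {b: directory / f"{b}.tif" for b in BAND_NAMES},
        directory / "sidecar.json",
    )


def write_raster(raster: ReflectanceRaster, path: str | Path) -> Path:
    """Write a 5-band float32 reflectance raster as a TIFF.

    Band order, nodata and any georeferencing pass-through are recorded as a
    JSON document in the TIFF ImageDescription tag.
    """
    path = Path(path)
    meta = {
        "band_order": list(raster.band_order),
        "nodata": raster.nodata,
        "geo": raster.geo,
    }
    tifffile.imwrite(
        path,
        raster.bands.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )
    return path


def read_raster(path: str | Path) -> ReflectanceRaster:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    if arr.ndim != 3 or arr.shape[0] != len(BAND_ORDER):
        raise SchemaError(
            f"{path}: expected {len(BAND_ORDER)}-band raster, got shape {arr.shape}"
        )
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    band_order = tuple(meta.get("band_order", BAND_ORDER))
    return ReflectanceRaster(
        bands=arr.astype(np.float32),
        band_order=band_order,
        nodata=float(meta.get("nodata", -9999.0)),
        geo=meta.get("geo", {}),
    )
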