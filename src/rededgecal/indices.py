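"""Vegetation indices, vegetation masking, and display composites.

Three normalised-difference indices over the reflectance bands:

* NDVI  = (nir - red) / (nir + red) — the classic greenness index, prone to
  saturation over dense canopy with narrow-band cameras.
* ReNDVI = (rededge - red) / (rededge + red) — the red-edge variant: the
  717 nm band sits on the red/NIR slope, widening the vegetation histogram
  and pulling non-vegetation below 0.1.
* NDRE = (nir - rededge) / (nir + rededge) — the established red-edge
  index, included for comparison; its values sit well below ReNDVI.

Composites are 8-bit displays after a pooled 2.5–97.5 percentile stretch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .capture import ReflectanceRaster

INDEX_BANDS = {
    "ndvi": ("nir", "red"),
    "rendvi": ("rededge", "red"),
    "ndre": ("nir", "rededge"),
}


@dataclass
class IndexRaster:
    """A normalised-difference index plane with NaN as nodata."""

    values: np.ndarray
    index_name: str

    def __post_init__(self) -> None:
        if self.index_name not in INDEX_BANDS:
            raise ValueError(f"unknown index {self.index_name!r}")
        self.values = np.asarray(self.values, dtype=np.float32)


def _normalized_difference(r: ReflectanceRaster, index_name: str) -> IndexRaster:
    hi_name, lo_name = INDEX_BANDS[index_name]
    hi = r.band(hi_name).astype(np.float64)
    lo = r.band(lo_name).astype(np.float64)
    valid = r.valid_mask()
    denom = hi + lo
    out = np.full(hi.shape, np.nan, dtype=np.float64)
    ok = valid & (denom != 0)
    out[ok] = (hi[ok] - lo[ok]) / denom[ok]
    return IndexRaster(values=out, index_name=index_name)


def ndvi(r: ReflectanceRaster) -> IndexRaster:
    """(nir - red) / (nir + red); zero-denominator pixels become nodata."""
    return _normalized_difference(r, "ndvi")


def rendvi(r: ReflectanceRaster) -> IndexRaster:
    """(rededge - red) / (rededge + red); the red-edge NDVI variant."""
    return _normalized_difference(r, "rendvi")


def ndre(r: ReflectanceRaster) -> IndexRaster:
    """(nir - rededge) / (nir + rededge)."""
    return _normalized_difference(r, "ndre")


def vegetation_mask(idx: IndexRaster, threshold: float = 0.1) -> np.ndarray:
    """Boolean vegetation mask: True where the index >= threshold.

    The default 0.1 cut on ReNDVI excludes water, bare soil, concrete and
    other non-vegetation surfaces. Nodata pixels are False.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        return np.asarray(idx.values >= threshold) & np.isfinite(idx.values)


def histogram_normalize(
    r: ReflectanceRaster,
    bands: tuple[str, str, str],
    lo_pct: float = 2.5,
    hi_pct: float = 97.5,
) -> np.ndarray:
    """Contrast-stretched 8-bit 3-plane composite.

    One (lo, hi) threshold pair is computed from the *pooled* pixels of all
    three requested bands — never per band, so the white balance between
    planes is preserved — then each plane is linearly stretched to [0, 255]
    with clipping. Percentiles use linear interpolation between order
    statistics. Nodata renders as 0.
    """
    if len(bands) != 3:
        raise ValueError("exactly 3 bands required for a composite")
    planes = [r.band(b) for b in bands]
    valid = r.valid_mask()
    pooled = np.concatenate([p[valid].ravel() for p in planes])
    if pooled.size == 0:
        raise ValueError("no valid pixels to normalize")
    lo, hi = np.percentile(pooled, [lo_pct, hi_pct])
    out = np.zeros((3,) + planes[0].shape, dtype=np.uint8)
    if hi == lo:
        warnings.warn("constant image: histogram stretch degenerate, rendering mid-gray")
        for i in range(3):
            out[i][valid] = 128
        return out
    for i, p in enumerate(planes):
        stretched = (p.astype(np.float64) - lo) / (hi - lo)
        out[i] = np.where(valid, np.clip(stretched, 0.0, 1.0) * 255.0, 0).astype(np.uint8)
    return out


COMPOSITE_ROUTING = {
    "rgb": ("red", "green", "blue"),
    "cir": ("nir", "red", "green"),  # false-color infrared: vegetation renders red
}


def composite(r: ReflectanceRaster, mode: str = "rgb") -> np.ndarray:
    """8-bit display composite: ``rgb`` = (red, green, blue); ``cir`` = (nir, red, green)."""
    try:
        routing = COMPOSITE_ROUTING[mode]
    except KeyError:
        raise ValueError(f"unknown composite mode {mode!r}") from None
    return histogram_normalize(r, routing)
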