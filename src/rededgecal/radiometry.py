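"""Raw DN to spectral radiance and CRP-panel reflectance conversion.

The sensor model converts a raw digital number plane to absolute spectral
radiance ``L`` (W/m²/sr/nm)::

    L = V(x, y) * (a1 / g) * (DN_norm - DNBL_norm) / (te + a2*y - a3*te*y)

where DN and the black level are normalised by 65536, ``te`` is exposure
time (s), ``g`` gain, and ``y`` the 0-based row index (the row term models
the rolling-shutter exposure gradient). ``V`` is the radial vignette gain::

    V(x, y) = 1 / (1 + k0*r + k1*r² + k2*r³ + k3*r⁴ + k4*r⁵ + k5*r⁶)

with ``r`` the distance in pixels from (x, y) to the optical centre
(cx, cy). Reflectance follows from the Calibrated Reflectance Panel:
``rho = (rho_CRP / L_CRP) * L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandDefinition
from .capture import RadiometricTags


@dataclass
class RadianceImage:
    """Per-pixel spectral radiance (W/m²/sr/nm) for one band.

    ``n_clamped`` counts pixels whose DN fell below the black level and were
    clamped to zero radiance — a QA signal for sensor anomalies.
    """

    values: np.ndarray
    band: BandDefinition
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def vignette_map(width: int, height: int, tags: RadiometricTags) -> np.ndarray:
    """Unitless vignette gain V(x, y) evaluated at every pixel centre.

    V equals 1 exactly at the optical centre and (for positive coefficients)
    falls off radially. Returned as a (height, width) float64 array.
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    k = np.asarray(tags.vignette_coeffs, dtype=np.float64)
    cx, cy = tags.vignette_center
    if not np.all(np.isfinite(k)):
        raise ValueError("vignette coefficients must be finite")
    x = np.arange(width, dtype=np.float64)
    y = np.arange(height, dtype=np.float64)
    r = np.hypot(x[None, :] - cx, y[:, None] - cy)
    # Horner evaluation of 1 + k0*r + ... + k5*r^6 = 1 + r*(k0 + r*(k1 + ...))
    poly = np.zeros_like(r)
    for coeff in k[::-1]:
        poly = r * (coeff + poly)
    return 1.0 / (1.0 + poly)


def row_denominator(tags: RadiometricTags, height: int) -> np.ndarray:
    """Per-row exposure denominator ``te + a2*y - a3*te*y`` (0-based rows)."""
    y = np.arange(height, dtype=np.float64)
    return tags.te + tags.a2 * y - tags.a3 * tags.te * y


def dn_to_radiance(
    plane: np.ndarray,
    tags: RadiometricTags,
    band: BandDefinition,
    *,
    clamp_negative: bool = True,
) -> RadianceImage:
    """Convert one raw uint16 DN plane to absolute spectral radiance.

    Negative radiance (DN below black level, possible with read noise) is
    clamped to 0 and counted in the result's QA field. A non-positive row
    denominator signals corrupt exposure tags and raises, naming the row.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError("plane must be 2-D")
    h, w = plane.shape
    denom = row_denominator(tags, h)
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive exposure denominator at row {bad[0]} "
            f"(te={tags.te}, a2={tags.a2}, a3={tags.a3}); tags look corrupt"
        )
    v = vignette_map(w, h, tags)
    dn_norm = plane.astype(np.float64) / tags.dn_scale
    bl_norm = tags.dn_black_level / tags.dn_scale
    radiance = v * (tags.a1 / tags.g) * (dn_norm - bl_norm) / denom[:, None]
    n_clamped = 0
    if clamp_negative:
        neg = radiance < 0
        n_clamped = int(neg.sum())
        if n_clamped:
            radiance = np.where(neg, 0.0, radiance)
    return RadianceImage(values=radiance, band=band, n_clamped=n_clamped)


def crp_reflectance(
    radiance: RadianceImage, l_crp: float, band: BandDefinition
) -> np.ndarray:
    """Reflectance from the panel ratio: ``rho = (rho_CRP / L_CRP) * L``.

    ``l_crp`` is the mean radiance extracted from the panel AOI of the same
    mission's calibration capture. Applying the conversion to the panel's
    own mean radiance returns the panel reflectance by construction.
    """
    if not np.isfinite(l_crp) or l_crp <= 0:
        raise ValueError(f"panel radiance must be positive, got {l_crp!r} "
                         "(invalid calibration image)")
    return (band.crp_reflectance / l_crp) * radiance.values
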