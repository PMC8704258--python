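"""Cross-sensor CRP–DLS regression and the per-mission correction factor.

The panel-derived irradiance and the DLS reading differ systematically
(ground path scattering, diffuser sensitivity) but track linearly::

    Irr_CRP = a * Irr_DLS + b

Fitting this per band over many calibration shots gives a universal model.
For one mission, with mean panel radiance ``L_CRP``, the multiplicative
correction applied to panel-based reflectance is::

    Cor = a / (1 - b * rho_CRP / (pi * L_CRP))

so that ``rho_cor = Cor * rho`` equals the reflectance referenced to the
DLS irradiance. As ``L_CRP`` grows the factor converges to the slope ``a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bands import BAND_NAMES, BandDefinition, get_band
from .capture import Capture, PanelSpec, ReflectanceRaster
from .panels import CalibrationError, CalibrationSample, collect_samples


@dataclass(frozen=True)
class RegressionModel:
    """Per-band linear map from DLS to panel-equivalent irradiance."""

    band: BandDefinition
    slope_a: float
    intercept_b: float  # W/m²/nm
    r_squared: float = float("nan")
    n_samples: int = 2

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("a regression needs at least 2 samples")

    def predict_irr_crp(self, irr_dls: float) -> float:
        return self.slope_a * irr_dls + self.intercept_b


# Packaged default models: the universal fit over 107 calibration shots
# spanning sunny and cloudy conditions (R² 0.995–0.997 per band).
DEFAULT_MODELS: dict[str, RegressionModel] = {
    name: RegressionModel(get_band(name), a, b, r_squared=float("nan"), n_samples=107)
    for name, a, b in (
        ("blue", 1.0118, 0.0036),
        ("green", 1.1290, 0.0073),
        ("red", 1.0875, 0.0210),
        ("rededge", 1.0674, 0.0015),
        ("nir", 1.2506, 0.0155),
    )
}


@dataclass(frozen=True)
class CorrectionFactor:
    """Per-band multiplicative reflectance correction for one mission."""

    band: BandDefinition
    factor: float
    l_crp_mission: float
    model: RegressionModel

    def __post_init__(self) -> None:
        if not (np.isfinite(self.factor) and self.factor > 0):
            raise ValueError(f"correction factor must be positive/finite, got {self.factor}")


def fit_crp_dls(
    samples: list[CalibrationSample],
    band: str | BandDefinition,
    *,
    robust: bool = False,
) -> RegressionModel:
    """Fit ``Irr_CRP = a * Irr_DLS + b`` for one band.

    Plain ordinary least squares by default; ``robust=True`` switches to a
    Theil–Sen estimator for outlier-heavy sample sets.
    """
    band = get_band(band) if isinstance(band, str) else band
    if len(samples) < 2:
        raise ValueError("need at least 2 calibration samples")
    x = np.array([s.irr_dls for s in samples], dtype=np.float64)
    y = np.array([s.irr_crp for s in samples], dtype=np.float64)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all DLS irradiance values identical")
    if robust:
        res = stats.theilslopes(y, x)
        a, b = float(res.slope), float(res.intercept)
    else:
        lr = stats.linregress(x, y)
        a, b = float(lr.slope), float(lr.intercept)
    resid = y - (a * x + b)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return RegressionModel(band, a, b, r_squared=r2, n_samples=len(samples))


def correction_factor(
    model: RegressionModel, l_crp_mission: float, band: str | BandDefinition | None = None
) -> CorrectionFactor:
    """Mission correction factor ``a / (1 - b*rho_CRP/(pi*L_CRP))``."""
    band = model.band if band is None else (get_band(band) if isinstance(band, str) else band)
    if l_crp_mission <= 0:
        raise CalibrationError("mission panel radiance must be positive")
    denom = 1.0 - model.intercept_b * band.crp_reflectance / (math.pi * l_crp_mission)
    if denom <= 0:
        raise CalibrationError(
            f"{band.name}: correction denominator {denom:.4g} <= 0 — the regression "
            "intercept dominates the panel radiance; calibration image invalid"
        )
    return CorrectionFactor(
        band=band, factor=model.slope_a / denom, l_crp_mission=l_crp_mission, model=model
    )


def correct_reflectance(
    raster: ReflectanceRaster, factors: dict[str, CorrectionFactor]
) -> ReflectanceRaster:
    """Apply per-band scalar factors: ``rho_cor = Cor * rho``; nodata preserved."""
    missing = [b for b in raster.band_order if b not in factors]
    if missing:
        raise ValueError(f"missing correction factors for bands: {missing}")
    out = raster.bands.copy()
    for i, name in enumerate(raster.band_order):
        plane = out[i]
        valid = plane != raster.nodata
        # float64 scalar multiply, stored back as float32
        plane[valid] = (plane[valid].astype(np.float64) * factors[name].factor).astype(
            np.float32
        )
    geo = dict(raster.geo)
    geo["correction_factors"] = {b: factors[b].factor for b in raster.band_order}
    return ReflectanceRaster(bands=out, band_order=raster.band_order,
                             nodata=raster.nodata, geo=geo)


def mission_factors(
    calib_captures: list[Capture],
    panel: PanelSpec,
    models: dict[str, RegressionModel] | None = None,
) -> tuple[dict[str, CorrectionFactor], dict]:
    """Per-band factors for one mission from its calibration captures.

    The mission panel radiance is the unweighted mean of the per-capture AOI
    means (pre- and post-flight shots weighted equally). Returns the factors
    and a machine-readable report.
    """
    models = DEFAULT_MODELS if models is None else models
    samples = collect_samples(calib_captures, panel)
    factors: dict[str, CorrectionFactor] = {}
    report: dict = {"bands": {}}
    for name in BAND_NAMES:
        if name not in models:
            raise ValueError(f"no regression model for band {name!r}")
        band_samples = samples[name]
        l_crp = float(np.mean([s.l_crp for s in band_samples]))
        cf = correction_factor(models[name], l_crp)
        factors[name] = cf
        report["bands"][name] = {
            "l_crp_mission": l_crp,
            "n_calibration_captures": len(band_samples),
            "slope_a": models[name].slope_a,
            "intercept_b": models[name].intercept_b,
            "factor": cf.factor,
        }
    return factors, report


def mission_correct(
    calib_captures: list[Capture],
    survey_reflectance: ReflectanceRaster,
    panel: PanelSpec,
    models: dict[str, RegressionModel] | None = None,
) -> tuple[ReflectanceRaster, dict]:
    """End-to-end mission correction: panel radiance → factors → corrected raster."""
    factors, report = mission_factors(calib_captures, panel, models)
    corrected = correct_reflectance(survey_reflectance, factors)
    return corrected, report
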