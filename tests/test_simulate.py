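"""Forward simulator: determinism, model inversion, and mission-level recovery."""

import numpy as np
import pytest

from rededgecal import (
    BAND_NAMES,
    Scenario,
    cloudy_scenario,
    default_panel_spec,
    default_scene,
    dn_to_radiance,
    fit_crp_dls,
    get_band,
    mission_factors,
    simulate_capture,
    simulate_mission,
    sunny_scenario,
    correct_reflectance,
)
from rededgecal.panels import SATURATION_DN, collect_samples
from rededgecal.pipeline import capture_to_reflectance
from rededgecal.simulate import CLASS_SPECTRA, VEGETATION_CLASSES, radiance_to_dn

from conftest import make_tags


class TestSimulateCapture:
    def test_same_seed_gives_identical_planes(self, scene):
        scn = Scenario(name="sunny", seed=42, noise_dn=20.0)
        cap1, _ = simulate_capture(scene, scn, 0.3, "survey")
        cap2, _ = simulate_capture(scene, scn, 0.3, "survey")
        for b in BAND_NAMES:
            np.testing.assert_array_equal(cap1.planes[b], cap2.planes[b])

    def test_continuous_forward_model_inverts_exactly(self, scene, noise_free_sunny):
        # unquantised counts: DN->radiance is the exact algebraic inverse
        _, truth = simulate_capture(scene, noise_free_sunny, 0.5, "survey")
        for b in BAND_NAMES:
            tags = make_tags(96, 72, a1=6e-4, a2=1e-7, a3=1e-5,
                             k=(1e-4, 1e-7, 0, 0, 0, 0))
            dn = radiance_to_dn(truth["radiance"][b], tags, quantize=False)
            rad = dn_to_radiance(dn, tags, get_band(b))
            np.testing.assert_allclose(rad.values, truth["radiance"][b], rtol=1e-6)

    def test_capture_round_trip_within_quantisation(self, scene, noise_free_sunny):
        cap, truth = simulate_capture(scene, noise_free_sunny, 0.5, "survey")
        for b in BAND_NAMES:
            rad = dn_to_radiance(cap.planes[b], cap.tags[b], get_band(b))
            rel = np.abs(rad.values - truth["radiance"][b]) / truth["radiance"][b]
            assert rel.max() < 2e-3  # half-count bound at the darkest class

    def test_calibration_panel_below_saturation_in_sunny_preset(self, scene):
        cap, _ = simulate_capture(scene, sunny_scenario(seed=0), 1.0, "calibration")
        panel = default_panel_spec(*scene.shape[::-1])
        r0, c0, r1, c1 = panel.aoi
        for b in BAND_NAMES:
            assert (cap.planes[b][r0:r1, c0:c1] < SATURATION_DN).all()

    def test_vegetation_spectra_obey_red_edge_ordering(self):
        for name in VEGETATION_CLASSES:
            s = CLASS_SPECTRA[name]
            assert s["nir"] > s["rededge"] > s["green"] > s["red"]


class TestSimulateMission:
    def test_mission_structure_and_files(self, scene, tmp_path):
        res = simulate_mission(scene, sunny_scenario(seed=3), n_calib=2,
                               n_survey=4, out_dir=tmp_path)
        assert len(res["captures"]) == 6
        roles = [c.role for c in res["captures"].values()]
        assert roles.count("calibration") == 2 and roles.count("survey") == 4
        assert (tmp_path / "manifest.json").exists()
        assert (tmp_path / "truth" / "reflectance.tif").exists()
        assert (tmp_path / "calib_000" / "sidecar.json").exists()

    def test_fit_recovers_true_sensor_offset_as_noise_vanishes(self, scene):
        scn = Scenario(name="sunny", seed=5, noise_dn=0.0,
                       irradiance_profile=lambda t: 0.5 + 1.3 * t)
        panel = default_panel_spec(*scene.shape[::-1])
        caps = [simulate_capture(scene, scn, t, "calibration", panel=panel)[0]
                for t in np.linspace(0, 1, 9)]
        samples = collect_samples(caps, panel)
        for b in BAND_NAMES:
            a_true, b_true = scn.sensor_offset[b]
            m = fit_crp_dls(samples[b], b)
            assert m.slope_a == pytest.approx(a_true, rel=1e-3)
            assert m.intercept_b == pytest.approx(b_true, abs=2e-3)

    @pytest.mark.parametrize("preset", ["sunny", "cloudy"])
    def test_correction_reduces_rmse_vs_truth(self, scene, preset):
        scn = Scenario(name=preset, seed=11, noise_dn=20.0)
        res = simulate_mission(scene, scn, n_calib=2, n_survey=2)
        calib = [c for c in res["captures"].values() if c.role == "calibration"]
        survey = [c for c in res["captures"].values() if c.role == "survey"]
        factors, rep = mission_factors(calib, res["panel"])
        l_crp = {b: rep["bands"][b]["l_crp_mission"] for b in BAND_NAMES}
        truth = res["truth_reflectance"].bands
        for cap in survey:
            raw = capture_to_reflectance(cap, l_crp)
            cor = correct_reflectance(raw, factors)
            rmse_raw = np.sqrt(np.mean((raw.bands - truth) ** 2))
            rmse_cor = np.sqrt(np.mean((cor.bands - truth) ** 2))
            assert rmse_cor < rmse_raw

    def test_noise_free_mission_recovers_truth_to_half_percent(
        self, scene, noise_free_sunny
    ):
        res = simulate_mission(scene, noise_free_sunny, n_calib=2, n_survey=1)
        calib = [c for c in res["captures"].values() if c.role == "calibration"]
        survey = [c for c in res["captures"].values() if c.role == "survey"]
        factors, rep = mission_factors(calib, res["panel"])
        l_crp = {b: rep["bands"][b]["l_crp_mission"] for b in BAND_NAMES}
        cor = correct_reflectance(capture_to_reflectance(survey[0], l_crp), factors)
        truth = res["truth_reflectance"].bands
        rel = np.abs(cor.bands - truth) / truth
        assert rel.max() < 0.005

    def test_cloudy_factors_exceed_sunny_factors_per_band(self, scene):
        out = {}
        for preset in ("sunny", "cloudy"):
            scn = Scenario(name=preset, seed=2, noise_dn=0.0)
            res = simulate_mission(scene, scn, n_calib=2, n_survey=0)
            calib = [c for c in res["captures"].values()]
            factors, _ = mission_factors(calib, res["panel"])
            out[preset] = factors
        for b in BAND_NAMES:
            assert out["cloudy"][b].factor >= out["sunny"][b].factor

    def test_eq7_factor_equals_dls_ratio_reflectance(self, scene):
        # algebraic consistency: Cor * rho_raw == L / L_DLS, noise-free
        scn = Scenario(name="sunny", seed=9, noise_dn=0.0,
                       irradiance_profile=lambda t: 1.2)
        panel = default_panel_spec(*scene.shape[::-1])
        cap, truth = simulate_capture(scene, scn, 0.5, "calibration", panel=panel)
        from rededgecal.correction import RegressionModel, correction_factor

        for b in BAND_NAMES:
            band = get_band(b)
            a_true, b_true = scn.sensor_offset[b]
            e_sky = truth["sky_irradiance"][b]
            l_crp = truth["panel_irradiance"][b] * band.crp_reflectance / np.pi
            model = RegressionModel(band, a_true, b_true)
            cor = correction_factor(model, l_crp).factor
            l_scene = truth["radiance"][b]
            rho_raw = band.crp_reflectance * l_scene / l_crp
            rho_dls = l_scene / (e_sky / np.pi)
            np.testing.assert_allclose(cor * rho_raw, rho_dls, rtol=1e-10)
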