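"""Localization fitting, astigmatism calibration, z lookup, band-pass."""

import numpy as np
import pandas as pd
import pytest

from septatrack import loc3d
from septatrack.loc3d import (GaussianFitError, bandpass_filter,
                              calibrate_astigmatism, fit_gaussian2d, lookup_z)
from septatrack.simcell import simulate_bead_stack


def _render(shape, x0, y0, sx, sy, amp=1000.0, bg=50.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return bg + amp * np.exp(-((xx - x0) ** 2 / (2 * sx**2)
                               + (yy - y0) ** 2 / (2 * sy**2)))


class TestGaussianFit:
    def test_symmetric_spot_recovered_exactly(self):
        # sigma 130 nm at 100 nm pixels = 1.3 px
        roi = _render((11, 11), 5.0, 5.0, 1.3, 1.3)
        res = fit_gaussian2d(roi, px_size=100.0)
        assert res["x"] == pytest.approx(5.0, abs=0.01)
        assert res["y"] == pytest.approx(5.0, abs=0.01)
        assert res["sigma1"] == pytest.approx(130.0, rel=1e-3)
        assert res["sigma2"] == pytest.approx(130.0, rel=1e-3)

    def test_subpixel_shift_recovered(self):
        roi = _render((11, 11), 5.3, 4.7, 1.3, 1.3)
        res = fit_gaussian2d(roi)
        assert res["x"] == pytest.approx(5.3, abs=0.05)
        assert res["y"] == pytest.approx(4.7, abs=0.05)

    def test_flat_patch_flagged(self):
        with pytest.raises(GaussianFitError):
            fit_gaussian2d(np.full((9, 9), 7.0))

    def test_rerendering_fit_reproduces_input(self):
        roi = _render((13, 13), 6.2, 5.9, 1.6, 1.1)
        res = fit_gaussian2d(roi)
        amp = res["intensity"] / (2 * np.pi * res["sigma1"] * res["sigma2"])
        yy, xx = np.mgrid[0:13, 0:13].astype(float)
        model = res["background"] + amp * np.exp(
            -((xx - res["x"]) ** 2 / (2 * max(res["sigma1"], res["sigma2"])**2)
              + (yy - res["y"]) ** 2 / (2 * min(res["sigma1"], res["sigma2"])**2)))
        assert np.allclose(model, roi, rtol=1e-3, atol=1e-2)


class TestCalibration:
    def test_noiseless_table_reproduced_at_nodes(self, psf_model, bead_calib):
        tab = simulate_bead_stack(sigma_model=psf_model)
        assert np.allclose(bead_calib.sigma1(tab.z), tab.sigma1, atol=1e-9)
        assert np.allclose(bead_calib.sigma2(tab.z), tab.sigma2, atol=1e-9)

    def test_noisy_table_smoothed_curve_within_noise_of_truth(self, psf_model):
        tab = simulate_bead_stack(noise=3.0, seed=9, sigma_model=psf_model)
        calib = calibrate_astigmatism(tab)
        true1 = psf_model.sigma1(tab.z)
        rms = np.sqrt(np.mean((calib.sigma1(tab.z) - true1) ** 2))
        assert rms <= 3.0

    def test_too_few_planes_rejected(self, psf_model):
        tab = simulate_bead_stack((-100, 100), 100, psf_model)
        assert len(tab) == 3
        with pytest.raises(ValueError):
            calibrate_astigmatism(tab)

    def test_nonmonotone_width_difference_rejected(self):
        z = np.linspace(-300, 300, 13)
        sig = 130 + 0.0001 * z**2  # sigma1 == sigma2: difference constant
        with pytest.raises(ValueError):
            calibrate_astigmatism(pd.DataFrame(
                {"z": z, "sigma1": sig, "sigma2": sig}))


class TestLookupZ:
    def test_crossing_point_maps_to_zero(self, psf_model, bead_calib):
        s0 = float(psf_model.sigma1(0.0))
        assert lookup_z(s0, s0, bead_calib) == pytest.approx(0.0, abs=0.5)

    def test_raw_100nm_rescaled_to_75(self, psf_model, bead_calib):
        z = lookup_z(psf_model.sigma1(100.0), psf_model.sigma2(100.0),
                     bead_calib)
        assert z == pytest.approx(75.0, abs=0.5)

    def test_bead_round_trip_within_10nm(self, psf_model):
        tab = simulate_bead_stack(noise=2.0, seed=4, sigma_model=psf_model)
        calib = calibrate_astigmatism(tab)
        z_true = np.linspace(-400, 400, 17)
        z_back = lookup_z(psf_model.sigma1(z_true), psf_model.sigma2(z_true),
                          calib)
        assert np.all(np.abs(z_back / 0.75 - z_true) < 10.0)

    def test_monotone_in_width_difference(self, psf_model, bead_calib):
        z_grid = np.linspace(-450, 450, 41)
        z_back = lookup_z(psf_model.sigma1(z_grid), psf_model.sigma2(z_grid),
                          bead_calib)
        assert np.all(np.diff(z_back) > 0)

    def test_widths_outside_envelope_dropped(self, bead_calib):
        assert np.isnan(lookup_z(600.0, 600.0, bead_calib))
        locs = pd.DataFrame({"frame": [0, 0], "x": [0, 0], "y": [0, 0],
                             "sigma1": [140.0, 700.0],
                             "sigma2": [140.0, 700.0],
                             "intensity": [1.0, 1.0]})
        out = loc3d.add_z(locs, bead_calib)
        assert len(out) == 1


class TestBandpass:
    @pytest.mark.parametrize("s1,s2,kept", [
        (50.0, 150.0, False),   # below the 60 nm bound
        (150.0, 150.0, True),   # within band
        (60.0, 60.0, True),     # inclusive boundary
        (300.0, 300.0, True),   # inclusive boundary
        (150.0, 310.0, False),  # above the 300 nm bound
    ])
    def test_band_boundaries(self, s1, s2, kept):
        locs = pd.DataFrame({"frame": [0], "x": [0.0], "y": [0.0],
                             "sigma1": [s1], "sigma2": [s2],
                             "intensity": [1.0]})
        assert (len(bandpass_filter(locs)) == 1) is kept

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(0)
        locs = pd.DataFrame({
            "frame": np.arange(100), "x": np.zeros(100), "y": np.zeros(100),
            "sigma1": rng.uniform(20, 400, 100),
            "sigma2": rng.uniform(20, 400, 100),
            "intensity": np.ones(100)})
        once = bandpass_filter(locs)
        twice = bandpass_filter(once)
        assert len(once) <= len(locs)
        pd.testing.assert_frame_equal(once, twice)


def test_thunderstorm_round_trip_converts_frame_base(tmp_path):
    locs = pd.DataFrame({"frame": [0, 4], "x": [10.0, 20.0],
                         "y": [1.0, 2.0], "sigma1": [130.0, 140.0],
                         "sigma2": [120.0, 150.0], "intensity": [900.0, 1100.0]})
    path = tmp_path / "locs.csv"
    loc3d.write_thunderstorm(locs, path)
    on_disk = pd.read_csv(path)
    assert list(on_disk["frame"]) == [1, 5]  # 1-based in files
    back = loc3d.read_thunderstorm(path)
    pd.testing.assert_frame_equal(back, locs, check_dtype=False)


def test_calibration_file_round_trip(tmp_path, psf_model, bead_calib):
    csv = tmp_path / "calib.csv"
    loc3d.write_calibration(bead_calib, csv)
    back = loc3d.read_calibration(csv)
    assert back.rescale_factor == bead_calib.rescale_factor
    z = np.linspace(-300, 300, 7)
    assert np.allclose(back.sigma1(z), bead_calib.sigma1(z))
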