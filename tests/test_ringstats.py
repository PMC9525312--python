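"""Ring ACF, midcell fraction, ring dimensions, pseudo time course."""

import numpy as np
import pytest

from septatrack.ringstats import (ACFCurve, RingProfile, mean_acf,
                                  pseudo_timecourse, ring_acf,
                                  ring_dimensions, ring_fraction)
from septatrack.simcell import simulate_torus_localizations


def brute_force_acf(z):
    """Independent double-loop evaluation of the pairwise sum."""
    n = len(z)
    denom = sum(zi * zi for zi in z)
    return np.array([sum(z[i] * z[i + k] for i in range(n - k)) / denom
                     for k in range(n)])


class TestRingACF:
    def test_uniform_profile_closed_form(self):
        acf = ring_acf(np.full(10, 3.7))
        assert acf.p[3] == pytest.approx(0.7)   # (N-k)/N
        assert np.allclose(acf.p, (10 - np.arange(10)) / 10)

    def test_delta_profile(self):
        z = np.zeros(20)
        z[7] = 5.0
        acf = ring_acf(z)
        assert acf.p[0] == 1.0
        assert np.allclose(acf.p[1:], 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = rng.integers(0, 50, 50).astype(float)
            if not z.any():
                continue
            assert np.allclose(ring_acf(z).p, brute_force_acf(z), atol=1e-12)

    def test_normalization_p0_is_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            z = rng.uniform(0, 10, 30)
            assert ring_acf(z).p[0] == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            ring_acf(np.zeros(10))

    def test_circular_variant_wraps(self):
        z = np.zeros(10)
        z[0] = z[9] = 1.0
        lin = ring_acf(z).p
        circ = ring_acf(z, circular=True).p
        assert lin[1] == 0.0        # neighbors only across the wrap
        assert circ[1] == 0.5       # one wrapped pair over sum Z^2 = 2

    def test_distance_axis_uses_bin_size(self):
        prof = RingProfile(z=np.ones(8), bin_size=25.0)
        acf = ring_acf(prof)
        assert acf.r[1] == 25.0


class TestMeanACF:
    def test_identical_curves_mean_is_curve_sem_zero(self):
        c = ring_acf(np.array([1.0, 2.0, 3.0, 1.0]))
        m = mean_acf([c, c, c])
        assert np.allclose(m.p, c.p)
        assert np.allclose(m.sem, 0.0)

    def test_two_curves_mean_is_midpoint(self):
        a = ACFCurve(np.arange(3.0), np.array([1.0, 0.2, 0.0]))
        b = ACFCurve(np.arange(3.0), np.array([1.0, 0.6, 0.4]))
        assert np.allclose(mean_acf([a, b]).p, [1.0, 0.4, 0.2])

    def test_mismatched_lengths_rejected(self):
        a = ACFCurve(np.arange(3.0), np.ones(3))
        b = ACFCurve(np.arange(4.0), np.ones(4))
        with pytest.raises(ValueError):
            mean_acf([a, b])


class TestRingFraction:
    @pytest.mark.parametrize("ring,whole,expect", [
        (100.0, 100.0, 1.0),
        (20.0, 100.0, 0.2),    # FtsN-like midcell share
        (45.0, 100.0, 0.45),   # FtsZ-like midcell share
    ])
    def test_values(self, ring, whole, expect):
        assert ring_fraction(ring, whole) == pytest.approx(expect)

    def test_zero_whole_rejected(self):
        with pytest.raises(ValueError):
            ring_fraction(1.0, 0.0)

    def test_bounded_when_ring_below_whole(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            whole = rng.uniform(1, 100)
            ring = rng.uniform(0, whole)
            assert 0.0 <= ring_fraction(ring, whole) <= 1.0


class TestRingDimensions:
    def test_sharp_torus_recovered_before_deconvolution(self):
        locs = simulate_torus_localizations(
            4000, diameter=600.0, width_fwhm=100.0, thickness_fwhm=60.0,
            seed=0)
        dims = ring_dimensions(locs)
        assert dims.diameter == pytest.approx(600.0, rel=0.02)
        assert dims.width_raw == pytest.approx(100.0, rel=0.10)
        assert dims.thickness_raw == pytest.approx(60.0, rel=0.15)

    def test_blurred_torus_deconvolved_within_10pct(self):
        # isotropic 80 nm FWHM blur so the radial spread stays Gaussian
        locs = simulate_torus_localizations(
            6000, diameter=600.0, width_fwhm=100.0, thickness_fwhm=60.0,
            blur_xy=80.0, blur_z=80.0, seed=1)
        dims = ring_dimensions(locs, resolution_xy=80.0, resolution_z=80.0)
        assert dims.width == pytest.approx(100.0, rel=0.10)
        assert dims.thickness == pytest.approx(60.0, rel=0.15)

    def test_measured_equal_resolution_gives_zero_with_warning(self):
        from septatrack.ringstats import _deconvolve_fwhm
        warnings = []
        out = _deconvolve_fwhm(50.0, 50.0, warnings, "width")
        assert out == 0.0 and warnings

    def test_measured_below_resolution_returns_raw_with_warning(self):
        from septatrack.ringstats import _deconvolve_fwhm
        warnings = []
        out = _deconvolve_fwhm(40.0, 50.0, warnings, "width")
        assert out == 40.0 and warnings

    def test_too_few_localizations_rejected(self):
        with pytest.raises(ValueError):
            ring_dimensions(np.zeros((10, 3)))


class TestPseudoTimecourse:
    def test_permutation_invariance_and_order(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(200, 900, 60)
        f = 0.2 * d / 900 + rng.normal(0, 0.01, 60)
        a = pseudo_timecourse(d, f)
        perm = rng.permutation(60)
        b = pseudo_timecourse(d[perm], f[perm])
        assert np.allclose(a["mean_fraction"], b["mean_fraction"])
        assert np.all(np.diff(a["diameter_mid"]) < 0)   # large rings first

    def test_binned_curve_tracks_generating_profile(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(200, 900, 400)
        truth = 0.05 + 0.15 * (d - 200) / 700   # assembly profile
        f = truth + rng.normal(0, 0.02, 400)
        tc = pseudo_timecourse(d, f, n_bins=6)
        expect = 0.05 + 0.15 * (tc["diameter_mid"] - 200) / 700
        assert np.all(np.abs(tc["mean_fraction"] - expect)
                      <= 3 * np.maximum(tc["sem"], 0.005))
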