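"""Phasor transform, calibration, filtering, pooling and the fit oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasorph.phasor import (
    IRFModel,
    PhasorImage,
    PhasorPoint,
    TCSPCStack,
    calibrate_phasor,
    decay_shape,
    fit_mono_lifetime,
    histogram_mode,
    mono_exp_phasor,
    phasor_transform,
    roi_phasor,
    wavelet_filter,
)

REP_RATE = 8.0e7
PERIOD = 1e9 / REP_RATE  # 12.5 ns
OMEGA = 2 * np.pi * REP_RATE * 1e-9


def _stack_from_decay(decay, shape=(1, 1)):
    counts = np.broadcast_to(decay, shape + (decay.size,)).copy()
    return TCSPCStack(counts=counts, bin_width=PERIOD / decay.size, rep_rate=REP_RATE)


def _uniform_image(g, s, shape=(8, 8), photons=100.0):
    ones = np.ones(shape)
    return PhasorImage(
        g=g * ones,
        s=s * ones,
        photons=photons * ones,
        harmonic=1,
        omega=OMEGA,
        valid=ones.astype(bool),
    )


class TestPhasorTransform:
    def test_delta_decay_maps_to_unit_point(self):
        # all counts in the first bin: the tau -> 0 limit
        decay = np.zeros(64)
        decay[0] = 1000
        img = phasor_transform(_stack_from_decay(decay))
        t0 = 0.5 * PERIOD / 64
        assert img.g[0, 0] == pytest.approx(np.cos(OMEGA * t0), abs=1e-12)
        assert img.s[0, 0] == pytest.approx(np.sin(OMEGA * t0), abs=1e-12)
        assert img.g[0, 0] == pytest.approx(1.0, abs=5e-3)

    def test_flat_decay_maps_to_origin(self):
        img = phasor_transform(_stack_from_decay(np.full(64, 10.0)))
        assert abs(img.g[0, 0]) < 1e-12
        assert abs(img.s[0, 0]) < 1e-12

    def test_omega_tau_one_gives_half_half(self):
        # closed form: g = 1/(1+(wt)^2), s = wt/(1+(wt)^2); wt = 1 -> (0.5, 0.5)
        tau = 1.0 / OMEGA  # ~1.989 ns at 80 MHz
        irf = IRFModel(center=0.5, sigma=0.05)
        shape = decay_shape(tau, irf, 512, PERIOD)
        img = phasor_transform(_stack_from_decay(shape * 1e7))
        measured = phasor_transform(
            _stack_from_decay(decay_shape(2.5, irf, 512, PERIOD) * 1e7)
        )
        cal = calibrate_phasor(
            img,
            PhasorPoint(measured.g[0, 0], measured.s[0, 0]),
            mono_exp_phasor(2.5, OMEGA),
        )
        assert cal.g[0, 0] == pytest.approx(0.5, abs=1e-3)
        assert cal.s[0, 0] == pytest.approx(0.5, abs=1e-3)

    def test_zero_photon_pixels_flagged_not_nan(self):
        counts = np.zeros((2, 2, 64))
        counts[0, 0, 5] = 10
        img = phasor_transform(
            TCSPCStack(counts=counts, bin_width=PERIOD / 64, rep_rate=REP_RATE)
        )
        assert img.valid[0, 0] and not img.valid[1, 1]
        assert np.isfinite(img.g).all() and np.isfinite(img.s).all()

    @pytest.mark.parametrize("harmonic", [0, -1, 32, 40])
    def test_invalid_harmonic_rejected(self, harmonic):
        with pytest.raises(ValueError):
            phasor_transform(_stack_from_decay(np.ones(64)), harmonic=harmonic)

    def test_intensity_scale_invariance(self):
        decay = decay_shape(3.0, IRFModel(1.0, 0.1), 64, PERIOD) * 1e4
        a = phasor_transform(_stack_from_decay(decay))
        b = phasor_transform(_stack_from_decay(decay * 7.5))
        assert a.g[0, 0] == pytest.approx(b.g[0, 0], rel=1e-12)
        assert a.s[0, 0] == pytest.approx(b.s[0, 0], rel=1e-12)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 4.0, 6.0])
    def test_semicircle_law_after_calibration(self, tau):
        """Calibrated mono-exponentials land on g^2 + s^2 = g for any tau."""
        irf = IRFModel(center=1.0, sigma=0.15)
        n_bins = 256
        ref_tau = 2.5
        measured = phasor_transform(
            _stack_from_decay(decay_shape(ref_tau, irf, n_bins, PERIOD) * 1e7)
        )
        img = phasor_transform(
            _stack_from_decay(decay_shape(tau, irf, n_bins, PERIOD) * 1e7)
        )
        cal = calibrate_phasor(
            img,
            PhasorPoint(measured.g[0, 0], measured.s[0, 0]),
            mono_exp_phasor(ref_tau, OMEGA),
        )
        expected = mono_exp_phasor(tau, OMEGA)
        assert abs(cal.g[0, 0] - expected.g) < 1e-3
        assert abs(cal.s[0, 0] - expected.s) < 1e-3
        assert abs(cal.g[0, 0] ** 2 + cal.s[0, 0] ** 2 - cal.g[0, 0]) < 1e-3

    def test_linear_combination_law(self):
        """A two-component decay's phasor is the photon-weighted convex
        combination of the pure phasors (brute-force summed-decay oracle)."""
        irf = IRFModel(center=1.0, sigma=0.1)
        n_bins = 512
        d1 = decay_shape(2.0, irf, n_bins, PERIOD)
        d2 = decay_shape(4.0, irf, n_bins, PERIOD)
        for w in (0.0, 0.25, 0.5, 0.8, 1.0):
            mix = w * d1 + (1 - w) * d2
            pm = phasor_transform(_stack_from_decay(mix * 1e8))
            p1 = phasor_transform(_stack_from_decay(d1 * 1e8))
            p2 = phasor_transform(_stack_from_decay(d2 * 1e8))
            assert pm.g[0, 0] == pytest.approx(
                w * p1.g[0, 0] + (1 - w) * p2.g[0, 0], abs=1e-9
            )
            assert pm.s[0, 0] == pytest.approx(
                w * p1.s[0, 0] + (1 - w) * p2.s[0, 0], abs=1e-9
            )


class TestCalibration:
    def test_identity_reference_leaves_image_unchanged(self):
        img = _uniform_image(0.4, 0.3)
        ref = PhasorPoint(0.7, 0.2)
        out = calibrate_phasor(img, ref, ref)
        np.testing.assert_allclose(out.g, img.g)
        np.testing.assert_allclose(out.s, img.s)

    def test_zero_modulus_reference_rejected(self):
        img = _uniform_image(0.4, 0.3)
        with pytest.raises(ValueError):
            calibrate_phasor(img, PhasorPoint(0.0, 0.0), PhasorPoint(0.5, 0.5))

    def test_zero_weight_reference_rejected(self):
        img = _uniform_image(0.4, 0.3)
        with pytest.raises(ValueError):
            calibrate_phasor(
                img, PhasorPoint(0.5, 0.4, weight=0.0), PhasorPoint(0.5, 0.5)
            )


class TestWaveletFilter:
    def test_constant_field_preserved(self):
        img = _uniform_image(0.42, 0.31, shape=(64, 64))
        out = wavelet_filter(img)
        np.testing.assert_allclose(out.g, img.g, atol=1e-9)
        np.testing.assert_allclose(out.s, img.s, atol=1e-9)

    def test_variance_reduced_and_mean_preserved_on_noisy_field(self, rng):
        # uniform field at ~50 counts/pixel: Poisson phasor noise
        shape = (128, 128)
        g = 0.35 + rng.normal(0, 0.08, shape)
        s = 0.45 + rng.normal(0, 0.08, shape)
        photons = rng.poisson(50, shape).astype(float)
        photons[photons == 0] = 1
        img = PhasorImage(
            g=g, s=s, photons=photons, harmonic=1, omega=OMEGA,
            valid=np.ones(shape, bool),
        )
        out = wavelet_filter(img)
        assert out.g.std() < 0.5 * img.g.std()
        assert out.s.std() < 0.5 * img.s.std()
        # photon-weighted mean moves by < 1% of the endpoint segment (~0.32)
        w = img.photons
        for a, b in ((img.g, out.g), (img.s, out.s)):
            before = (a * w).sum() / w.sum()
            after = (b * w).sum() / w.sum()
            assert abs(after - before) < 0.01 * 0.32
        np.testing.assert_array_equal(out.photons, img.photons)

    def test_excessive_levels_rejected(self):
        img = _uniform_image(0.4, 0.3, shape=(16, 16))
        with pytest.raises(ValueError):
            wavelet_filter(img, levels=10)


class TestRoiPhasor:
    def _image(self, points, photons):
        n = len(points)
        g = np.array([[p[0] for p in points]])
        s = np.array([[p[1] for p in points]])
        ph = np.array([photons])
        return PhasorImage(
            g=g, s=s, photons=np.asarray(ph, float), harmonic=1, omega=OMEGA,
            valid=np.ones((1, n), bool),
        )

    def test_single_pixel_returns_that_phasor_with_zero_spread(self):
        img = self._image([(0.3, 0.4)], [50.0])
        pt, spread = roi_phasor(img, np.ones((1, 1), bool))
        assert (pt.g, pt.s, spread) == (0.3, 0.4, 0.0)
        assert pt.weight == 50.0

    def test_equal_photons_give_midpoint(self):
        img = self._image([(0.2, 0.5), (0.6, 0.1)], [100.0, 100.0])
        pt, _ = roi_phasor(img, np.ones((1, 2), bool))
        assert (pt.g, pt.s) == pytest.approx((0.4, 0.3))

    def test_weighted_mean_quarter_point(self):
        # photons 100 and 300: mean lies 1/4 along P2 -> P1 from P2
        img = self._image([(0.2, 0.5), (0.6, 0.1)], [100.0, 300.0])
        pt, _ = roi_phasor(img, np.ones((1, 2), bool))
        assert (pt.g, pt.s) == pytest.approx((0.5, 0.2))

    def test_empty_mask_rejected(self):
        img = self._image([(0.2, 0.5)], [10.0])
        with pytest.raises(ValueError):
            roi_phasor(img, np.zeros((1, 1), bool))


class TestHistogramMode:
    def test_uniform_field_mode_is_field_value(self):
        img = _uniform_image(0.423, 0.317)
        pt = histogram_mode(img, bin_width=0.01)
        assert abs(pt.g - 0.423) <= 0.005 + 1e-12
        assert abs(pt.s - 0.317) <= 0.005 + 1e-12

    def test_majority_population_wins(self, rng):
        shape = (10, 10)
        g = np.full(shape, 0.2)
        s = np.full(shape, 0.2)
        g.flat[:10] = 0.7  # 10% contaminant well separated
        s.flat[:10] = 0.5
        img = PhasorImage(
            g=g, s=s, photons=np.full(shape, 10.0), harmonic=1, omega=OMEGA,
            valid=np.ones(shape, bool),
        )
        pt = histogram_mode(img, bin_width=0.01)
        assert pt.g == pytest.approx(0.2, abs=0.005)

    def test_noisy_field_mode_near_truth(self, rng):
        shape = (128, 128)
        img = PhasorImage(
            g=0.4 + rng.normal(0, 0.02, shape),
            s=0.3 + rng.normal(0, 0.02, shape),
            photons=np.full(shape, 60.0),
            harmonic=1,
            omega=OMEGA,
            valid=np.ones(shape, bool),
        )
        pt = histogram_mode(img, bin_width=0.01)
        assert abs(pt.g - 0.4) < 0.01
        assert abs(pt.s - 0.3) < 0.01

    def test_no_valid_pixels_rejected(self):
        img = _uniform_image(0.4, 0.3, shape=(2, 2))
        img.valid[:] = False
        with pytest.raises(ValueError):
            histogram_mode(img)


class TestMonoLifetimeFit:
    @pytest.mark.parametrize("tau,tol", [(4.0, 0.1), (2.0, 0.05)])
    def test_round_trip_recovery(self, tau, tol, rng, irf):
        shape = decay_shape(tau, irf, 64, PERIOD)
        decay = rng.poisson(shape * 1e5)
        fit = fit_mono_lifetime(decay, irf, PERIOD / 64, REP_RATE)
        assert fit == pytest.approx(tau, abs=tol)

    def test_all_zero_decay_rejected(self, irf):
        with pytest.raises(ValueError):
            fit_mono_lifetime(np.zeros(64), irf, PERIOD / 64, REP_RATE)

    def test_too_few_counts_rejected(self, irf):
        decay = np.zeros(64)
        decay[3] = 50
        with pytest.raises(ValueError):
            fit_mono_lifetime(decay, irf, PERIOD / 64, REP_RATE)


@settings(max_examples=30, deadline=None)
@given(
    tau=st.floats(0.3, 8.0),
    scale=st.floats(0.1, 100.0),
)
def test_transform_scale_invariance_property(tau, scale):
    """Multiplying counts by any positive constant leaves (g, s) unchanged."""
    decay = decay_shape(tau, IRFModel(0.8, 0.1), 64, PERIOD) * 1e5
    a = phasor_transform(_stack_from_decay(decay))
    b = phasor_transform(_stack_from_decay(decay * scale))
    assert a.g[0, 0] == pytest.approx(b.g[0, 0], rel=1e-9)
    assert a.s[0, 0] == pytest.approx(b.s[0, 0], rel=1e-9)
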