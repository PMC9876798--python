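"""Characterization metrics: FWHM, accuracy, dynamic range, CNR, SNR,
penetration depth, bandwidth, insertion loss, relative resistance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import echopatch as ep
from echopatch.errors import MetricError


class TestFwhm:
    def test_gaussian(self):
        x = np.arange(-5, 5, 0.01)
        y = np.exp(-x**2 / 2.0)          # sigma = 1 mm at 0.01 mm spacing
        assert ep.fwhm(y, 0.01) == pytest.approx(2.355, rel=0.005)

    def test_rectangle(self):
        y = np.zeros(100)
        y[40:60] = 1.0                   # width 20 samples
        assert ep.fwhm(y, 1.0) == pytest.approx(20.0, abs=1.0)

    def test_bimodal_equal_peaks_rejected(self):
        y = np.zeros(50)
        y[10] = y[40] = 1.0
        with pytest.raises(MetricError):
            ep.fwhm(y, 1.0)

    def test_boundary_peak_rejected(self):
        y = np.linspace(0, 1, 20)
        with pytest.raises(MetricError):
            ep.fwhm(y, 1.0)


class TestElevationalResolution:
    def test_y_sweep_fwhm_matches_directivity(self, array):
        """Peak image amplitude vs scatterer elevational offset has a
        FWHM set by the two-way 2.3 mm element-length directivity
        (≈ 7 mm at 50 mm depth for this array)."""
        seq = ep.make_plane_sequence(array, [0.0])
        grid = ep.PixelGrid(4e-3, 4e-3, 41, 41, z_start=48e-3)
        y_offsets = np.linspace(-9e-3, 9e-3, 13)
        peaks = []
        for y in y_offsets:
            ph = ep.Phantom(positions=[[0.0, y, 50e-3]], reflectivity=[1.0])
            ch = ep.simulate_channel_data(ph, array, seq)
            frame = ep.das_beamform(ch, grid)
            peaks.append(np.abs(frame.values).max())
        width = ep.elevational_profile(np.array(peaks), y_offsets)
        lam = 1540.0 / array.centre_frequency
        # two-way directivity sinc²(L·y/(λz)) falls to 1/2 where
        # sinc(v) = 1/sqrt(2), i.e. v ≈ 0.4429
        expected = 2 * 0.4429 * lam * 50e-3 / array.element_length
        assert width == pytest.approx(expected, rel=0.15)

    def test_nonuniform_offsets_rejected(self):
        with pytest.raises(MetricError):
            ep.elevational_profile(np.array([0.1, 1.0, 0.1]),
                                   np.array([0.0, 1.0, 3.0]))


class TestLocationAccuracy:
    @pytest.mark.parametrize("computed,truth,expected", [
        (9.6, 10.0, 0.96), (10.0, 10.0, 1.0), (10.4, 10.0, 0.96),
    ])
    def test_reference_values(self, computed, truth, expected):
        assert ep.location_accuracy(computed, truth) == pytest.approx(expected)

    def test_zero_truth_rejected(self):
        with pytest.raises(MetricError):
            ep.location_accuracy(1.0, 0.0)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(1e-3, 1e3), st.floats(0.5, 1.5))
    def test_invariant_under_common_rescaling(self, scale, ratio):
        a1 = ep.location_accuracy(ratio * 10.0, 10.0)
        a2 = ep.location_accuracy(scale * ratio * 10.0, scale * 10.0)
        assert a1 == pytest.approx(a2, rel=1e-9)


class TestDynamicRange:
    def test_printed_grey_extremes_give_63_2(self):
        span, (c0, c255) = ep.dynamic_range([-15.0, 15.0], [38.7, 159.8])
        assert round(span, 1) == 63.2
        assert c255 - c0 == pytest.approx(span)

    def test_exact_endpoint_points(self):
        span, (c0, c255) = ep.dynamic_range([-24.0, 39.2], [0.0, 255.0])
        assert span == pytest.approx(63.2, abs=1e-9)
        assert c0 == pytest.approx(-24.0) and c255 == pytest.approx(39.2)

    def test_collinear_third_point_no_change(self):
        two, _ = ep.dynamic_range([-15.0, 15.0], [38.7, 159.8])
        m = (159.8 - 38.7) / 30.0
        mid = 38.7 + m * 15.0
        three, _ = ep.dynamic_range([-15.0, 0.0, 15.0], [38.7, mid, 159.8])
        assert three == pytest.approx(two, rel=1e-12)

    def test_negative_slope_rejected(self):
        with pytest.raises(MetricError):
            ep.dynamic_range([-15.0, 15.0], [200.0, 100.0])

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.5, 20.0), st.floats(-50.0, 150.0), st.integers(0, 2**31 - 1))
    def test_equals_255_over_slope(self, slope, intercept, seed):
        """Closed form 255/m against the least-squares fit on collinear points."""
        rng = np.random.default_rng(seed)
        c = np.sort(rng.uniform(-20, 20, 6))
        g = slope * c + intercept
        span, _ = ep.dynamic_range(c, g)
        assert span == pytest.approx(255.0 / slope, rel=1e-9)


class TestCnr:
    def test_identical_statistics_zero(self):
        rng = np.random.default_rng(0)
        img = rng.rayleigh(1.0, (40, 80))
        m_in = np.zeros_like(img, bool); m_in[:, :40] = True
        m_out = ~m_in
        img[:, 40:] = img[:, :40]
        assert ep.cnr(img, m_in, m_out) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        img = np.zeros((2, 4))
        img[:, :2] = [[9.0, 11.0], [11.0, 9.0]]     # mean 10, var 1
        img[:, 2:] = [[5.0, 7.0], [7.0, 5.0]]       # mean 6, var 1
        m_in = np.zeros_like(img, bool); m_in[:, :2] = True
        assert ep.cnr(img, m_in, ~m_in) == pytest.approx(4.0 / np.sqrt(2.0))

    def test_overlapping_rois_rejected(self):
        img = np.ones((4, 4))
        m = np.ones_like(img, bool)
        with pytest.raises(MetricError):
            ep.cnr(img, m, m)


class TestSnr:
    def _bmode(self, peak_lin=10.0, noise_rms=1.0, seed=1):
        rng = np.random.default_rng(seed)
        grid = ep.PixelGrid(20e-3, 20e-3, 81, 81, z_start=40e-3)
        env = np.abs(rng.normal(0, noise_rms, (81, 81)))
        env[40, 40] = peak_lin
        db = 20 * np.log10(env / env.max())
        return ep.BModeImage(grid=grid, intensity_db=np.clip(db, -120, 0), floor_db=-120.0)

    def test_peak_over_noise(self):
        bm = self._bmode()
        X, Z = np.meshgrid(bm.grid.x, bm.grid.z)
        roi = X > 5e-3
        snr = ep.snr_depth(bm, [(0.0, 50e-3)], roi).snr_db.iloc[0]
        noise = ep.rms(bm.linear[roi])
        assert snr == pytest.approx(20 * np.log10(bm.linear[40, 40] / noise))

    def test_scale_invariance(self):
        """SNR is a ratio: image normalization cannot change it."""
        a = self._bmode(peak_lin=10.0, noise_rms=1.0, seed=2)
        b = self._bmode(peak_lin=50.0, noise_rms=5.0, seed=2)
        X, Z = np.meshgrid(a.grid.x, a.grid.z)
        roi = X > 5e-3
        sa = ep.snr_depth(a, [(0.0, 50e-3)], roi).snr_db.iloc[0]
        sb = ep.snr_depth(b, [(0.0, 50e-3)], roi).snr_db.iloc[0]
        assert sa == pytest.approx(sb, abs=1e-6)

    def test_empty_roi_rejected(self):
        bm = self._bmode()
        with pytest.raises(MetricError):
            ep.snr_depth(bm, [(0.0, 50e-3)], np.zeros((81, 81), bool))


class TestPenetrationDepth:
    def _wire_image(self, visible_depths_mm, buried_depths_mm, seed=0):
        # gently fluctuating noise floor; buried wires are simply absent
        rng = np.random.default_rng(seed)
        grid = ep.PixelGrid(140e-3, 40e-3, 281, 81)
        env = 0.01 * (1.0 + 0.1 * rng.normal(0, 1.0, (281, 81)))
        wires = []
        for zmm in visible_depths_mm:
            iz = np.argmin(np.abs(grid.z - zmm * 1e-3))
            env[iz, 40] = 1.0
            wires.append((0.0, zmm * 1e-3))
        for zmm in buried_depths_mm:
            wires.append((0.0, zmm * 1e-3))
        db = np.clip(20 * np.log10(env / env.max()), -80, 0)
        return ep.BModeImage(grid=grid, intensity_db=db, floor_db=-80.0), wires

    def test_deepest_visible_wire(self):
        bm, wires = self._wire_image([40, 80, 120], [130, 140])
        assert ep.penetration_depth(bm, wires) == pytest.approx(120e-3)

    def test_all_visible(self):
        bm, wires = self._wire_image([40, 80, 120, 140], [])
        assert ep.penetration_depth(bm, wires) == pytest.approx(140e-3)

    def test_zero_margin_returns_deepest_detected(self):
        bm, wires = self._wire_image([40, 80], [])
        assert ep.penetration_depth(bm, wires, margin_db=0.0) == pytest.approx(80e-3)


class TestFractionalBandwidth:
    def test_recovers_synthesis_parameter(self):
        """The −6 dB bandwidth written into the pulse comes back out."""
        from echopatch.acoustics import pulse_kernel
        k, _ = pulse_kernel(ep.Pulse(3e6, 0.55), 40e6)
        assert ep.fractional_bandwidth(k, 40e6) == pytest.approx(0.55, rel=0.02)

    def test_pure_tone_near_zero(self):
        t = np.arange(4096) / 20e6
        tone = np.sin(2 * np.pi * 3e6 * t)
        bw = ep.fractional_bandwidth(tone, 20e6)
        assert bw < 0.02

    def test_fwhm_equal_centre_gives_unity(self):
        """A band whose spectral FWHM equals its centre frequency."""
        fs = 100.0
        f = np.fft.rfftfreq(16384, 1 / fs)
        sigma = 10.0 / (2 * np.sqrt(2 * np.log(2)))   # FWHM 10 Hz at fc 10 Hz
        wave = np.fft.irfft(np.exp(-((f - 10.0) ** 2) / (2 * sigma ** 2)))
        wave = np.roll(wave, wave.size // 2)          # centre the wrapped pulse
        assert ep.fractional_bandwidth(wave, fs) == pytest.approx(1.0, rel=0.05)


class TestInsertionLoss:
    def test_formula_collapse(self):
        assert ep.insertion_loss(1.0, 1.0, 0.0, 3.0) == pytest.approx(1.9)

    def test_tenth_voltage(self):
        assert ep.insertion_loss(0.1, 1.0, 0.0, 3.0) == pytest.approx(18.1)

    def test_with_water_path(self):
        assert ep.insertion_loss(0.1, 1.0, 40.0, 3.0) == pytest.approx(17.9416, abs=1e-4)

    def test_nonpositive_voltage_rejected(self):
        with pytest.raises(MetricError):
            ep.insertion_loss(0.0, 1.0, 0.0, 3.0)


class TestRelativeResistance:
    def test_breaking_point_value(self):
        assert round(ep.relative_resistance(44.87, 1.74), 2) == 25.79

    def test_identity_and_doubling(self):
        assert ep.relative_resistance(1.74, 1.74) == pytest.approx(1.0)
        assert ep.relative_resistance(3.48, 1.74) == pytest.approx(2.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(MetricError):
            ep.relative_resistance(1.0, 0.0)
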