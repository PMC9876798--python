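"""Cardiac-function pipeline: tracking, LVID, volumes, indices, agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import echopatch as ep
from echopatch.errors import CardiacError


def synthetic_mmode(near_fn, far_fn, n_frames=120, fps=30.0, line_sigma=0.8e-3):
    grid_z = np.linspace(5e-3, 105e-3, 401)
    times = np.arange(n_frames) / fps
    img = np.full((401, n_frames), 1e-4)
    for j, t in enumerate(times):
        for zc in (near_fn(t), far_fn(t)):
            img[:, j] += np.exp(-((grid_z - zc) ** 2) / (2 * line_sigma ** 2))
    db = np.clip(20 * np.log10(img / img.max()), -60, 0)
    return ep.MModeImage(z=grid_z, times=times, intensity_db=db, scanline_x=0.0)


class TestTrackInterfaces:
    def test_static_lines(self):
        mm = synthetic_mmode(lambda t: 30e-3, lambda t: 80e-3, n_frames=20)
        tr = ep.track_interfaces(mm, 30e-3, 80e-3)
        assert np.max(np.abs(tr.near - 30e-3)) < 0.3e-3
        assert np.max(np.abs(tr.far - 80e-3)) < 0.3e-3

    def test_sinusoidal_amplitude_recovery(self):
        f = 1.25
        mm = synthetic_mmode(lambda t: 30e-3 + 2e-3 * np.sin(2 * np.pi * f * t),
                             lambda t: 75e-3 - 6e-3 * np.sin(2 * np.pi * f * t))
        tr = ep.track_interfaces(mm, 30e-3, 75e-3)
        amp_near = 0.5 * np.ptp(tr.near)
        amp_far = 0.5 * np.ptp(tr.far)
        assert amp_near == pytest.approx(2e-3, rel=0.10)
        assert amp_far == pytest.approx(6e-3, rel=0.10)

    def test_init_outside_image_rejected(self):
        mm = synthetic_mmode(lambda t: 30e-3, lambda t: 80e-3, n_frames=10)
        with pytest.raises(CardiacError):
            ep.track_interfaces(mm, 1e-3, 200e-3)


class TestLvidWaveforms:
    def test_constant_lvid_degenerate_cycle(self):
        tr = ep.InterfaceTracks(times=np.arange(10) / 10.0,
                                near=np.full(10, 30e-3), far=np.full(10, 70e-3),
                                confidence=np.ones(10))
        cyc = ep.lvid_waveforms(tr)
        assert len(cyc) == 1
        assert cyc.lvidd_m.iloc[0] == pytest.approx(40e-3)
        assert cyc.lvids_m.iloc[0] == pytest.approx(40e-3)

    def test_sinusoid_extrema(self):
        t = np.arange(300) / 100.0
        lvid = (40.0 + 10.0 * np.sin(2 * np.pi * 1.0 * t)) * 1e-3
        tr = ep.InterfaceTracks(times=t, near=np.full_like(t, 20e-3),
                                far=20e-3 + lvid, confidence=np.ones_like(t))
        cyc = ep.lvid_waveforms(tr)
        assert np.allclose(cyc.lvidd_m, 50e-3, atol=0.1e-3)
        assert np.allclose(cyc.lvids_m, 30e-3, atol=0.1e-3)

    def test_per_cycle_drift_recovery(self):
        """Cycle-to-cycle amplitude drift is tracked per cycle."""
        fps, f = 100.0, 1.0
        t = np.arange(500) / fps
        amp = (8.0 + 2.0 * np.floor(t * f) / 5.0) * 1e-3   # grows each cycle
        lvid = 40e-3 - amp * (0.5 - 0.5 * np.cos(2 * np.pi * f * t))
        tr = ep.InterfaceTracks(times=t, near=np.full_like(t, 20e-3),
                                far=20e-3 + lvid, confidence=np.ones_like(t))
        cyc = ep.lvid_waveforms(tr)
        assert len(cyc) >= 3
        lvids = cyc.lvids_m.to_numpy()
        assert np.all(np.diff(lvids) < 0)                  # deeper each cycle
        expected_first = 40e-3 - (8.0 + 2.0 * 0.0 / 5.0) * 1e-3
        assert lvids[0] == pytest.approx(expected_first, rel=0.05)


class TestFractionalShortening:
    @pytest.mark.parametrize("lvidd,lvids,expected",
                             [(50.0, 30.0, 0.40), (40.0, 40.0, 0.0), (48.0, 30.0, 0.375)])
    def test_values(self, lvidd, lvids, expected):
        assert ep.fractional_shortening(lvidd, lvids) == pytest.approx(expected)

    def test_inverted_diameters_rejected(self):
        with pytest.raises(CardiacError):
            ep.fractional_shortening(30.0, 50.0)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(10.0, 80.0), st.floats(0.01, 1.0))
    def test_bounded_in_unit_interval(self, lvidd, frac):
        lvids = lvidd * frac
        fs = ep.fractional_shortening(lvidd, lvids)
        assert 0.0 <= fs < 1.0


class TestVolumeFromMask:
    def _ellipse_mask(self, a, b, px, tilt_deg=0.0):
        n_r = int(2 * (a + 4e-3) / px)
        n_c = int(2 * (a + 4e-3) / px)
        r = (np.arange(n_r) - (n_r - 1) / 2) * px
        c = (np.arange(n_c) - (n_c - 1) / 2) * px
        R, C = np.meshgrid(r, c, indexing="ij")
        th = np.radians(tilt_deg)
        u = R * np.cos(th) + C * np.sin(th)
        v = -R * np.sin(th) + C * np.cos(th)
        return (u**2 / a**2 + v**2 / b**2) <= 1.0

    def test_prolate_spheroid_closed_form(self):
        a, b, px = 40e-3, 20e-3, 0.2e-3
        mask = self._ellipse_mask(a, b, px)
        truth = 4.0 / 3.0 * np.pi * a * b**2 * 1e6
        assert ep.volume_from_mask(mask, px, n_disks=200) == pytest.approx(truth, rel=0.02)

    def test_principal_axis_handles_tilt(self):
        a, b, px = 35e-3, 18e-3, 0.2e-3
        truth = 4.0 / 3.0 * np.pi * a * b**2 * 1e6
        tilted = ep.volume_from_mask(self._ellipse_mask(a, b, px, tilt_deg=25.0),
                                     px, n_disks=100)
        assert tilted == pytest.approx(truth, rel=0.03)

    def test_empty_mask_zero(self):
        assert ep.volume_from_mask(np.zeros((50, 50), bool), 0.2e-3) == 0.0

    def test_scale_consistency(self):
        a, b = 30e-3, 15e-3
        coarse = ep.volume_from_mask(self._ellipse_mask(a, b, 0.4e-3), 0.4e-3, n_disks=100)
        fine = ep.volume_from_mask(self._ellipse_mask(a, b, 0.2e-3), 0.2e-3, n_disks=100)
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_area_length_on_ellipse(self):
        a, b, px = 40e-3, 20e-3, 0.2e-3
        truth = 4.0 / 3.0 * np.pi * a * b**2 * 1e6
        est = ep.volume_from_mask(self._ellipse_mask(a, b, px), px, method="area-length")
        assert est == pytest.approx(truth, rel=0.02)


class TestIndicesFromWaveform:
    def _waveform(self, edv=120.0, esv=50.0, hr=75.0, fps=50.0, n_cycles=4):
        period = 60.0 / hr
        t = np.arange(int(n_cycles * period * fps)) / fps
        v = esv + (edv - esv) * 0.5 * (1 + np.cos(2 * np.pi * t / period))
        return t, v

    def test_reference_cycle(self):
        t, v = self._waveform()
        idx = ep.indices_from_waveform(t, v)
        assert np.allclose(idx.edv_ml, 120.0, atol=0.5)
        assert np.allclose(idx.esv_ml, 50.0, atol=0.5)
        assert np.allclose(idx.sv_ml, idx.edv_ml - idx.esv_ml)
        assert np.allclose(idx.ef_pct, 100 * idx.sv_ml / idx.edv_ml)
        assert np.allclose(idx.hr_bpm, 75.0, atol=1.0)

    def test_printed_cardiac_output_level(self):
        """SV 70 ml at HR 130 bpm corresponds to about 9 l/min."""
        t, v = self._waveform(edv=120.0, esv=50.0, hr=130.0, fps=100.0)
        idx = ep.indices_from_waveform(t, v)
        assert np.allclose(idx.co_lpm, 70.0 * 130.0 / 1000.0, atol=0.3)
        assert idx.co_lpm.mean() == pytest.approx(9.1, abs=0.3)

    def test_identities_exact(self):
        t, v = self._waveform(hr=60.0)
        idx = ep.indices_from_waveform(t, v)
        assert np.all(idx.sv_ml == idx.edv_ml - idx.esv_ml)
        assert np.allclose(idx.co_lpm, idx.sv_ml * idx.hr_bpm / 1000.0)

    def test_constant_volume_rejected(self):
        with pytest.raises(CardiacError):
            ep.indices_from_waveform(np.arange(10.0), np.full(10, 80.0))


class TestHeartRate:
    @pytest.mark.parametrize("period,expected", [(0.5, 120.0), (1.0, 60.0)])
    def test_periodic_signal(self, period, expected):
        fps = 100.0
        t = np.arange(int(5 * period * fps)) / fps
        hr, inst = ep.heart_rate(np.sin(2 * np.pi * t / period), 1 / fps)
        assert hr == pytest.approx(expected, abs=1.0)
        # per-beat estimates are quantized by the frame interval
        quant = expected - 60.0 / (period + 1.0 / fps)
        assert np.all(np.abs(inst - expected) <= quant + 0.1)

    def test_single_peak_rejected(self):
        x = np.exp(-np.linspace(-3, 3, 50) ** 2)
        with pytest.raises(CardiacError):
            ep.heart_rate(x, 0.01)


class TestBlandAltman:
    def test_identical_methods(self):
        a = np.array([10.0, 20.0, 30.0])
        ba = ep.bland_altman(a, a)
        assert ba.mean_difference == 0.0
        assert ba.lower_limit == ba.upper_limit == 0.0

    def test_constant_offset(self):
        a = np.array([10.0, 20.0, 30.0])
        ba = ep.bland_altman(a, a + 3.0)
        assert ba.mean_difference == pytest.approx(-3.0)
        assert ba.sd_difference == pytest.approx(0.0)

    def test_limits_symmetric(self):
        rng = np.random.default_rng(3)
        a = rng.normal(100, 10, 50)
        b = a + rng.normal(0.5, 2.0, 50)
        ba = ep.bland_altman(a, b)
        assert (ba.upper_limit - ba.mean_difference) == pytest.approx(
            ba.mean_difference - ba.lower_limit)
        assert len(ba.table) == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(CardiacError):
            ep.bland_altman([1.0, 2.0], [1.0])
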