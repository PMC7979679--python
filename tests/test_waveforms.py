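import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsetwin.waveforms import (ResampledCycle, WaveformRecord,
                                 extract_features, harmonic_energy_fraction,
                                 heart_femoral_pwv, resample_cycle,
                                 waveform_accuracy)


def _record(pressure, T=1.0, site="test"):
    n = len(pressure)
    return WaveformRecord(site=site, time=np.arange(n) * T / n,
                          pressure_mmhg=np.asarray(pressure, dtype=float))


class TestResample:
    def test_constant_input_stays_constant(self):
        rec = _record(np.full(64, 80.0))
        out = resample_cycle(rec, 200)
        assert out.n == 200
        assert np.allclose(out.pressure_mmhg, 80.0)

    def test_sinusoid_round_trip_error_small(self):
        n = 256
        t = np.arange(n) / n
        rec = _record(10.0 * np.sin(2 * np.pi * t) + 90.0)
        out = resample_cycle(rec, 200)
        expected = 10.0 * np.sin(2 * np.pi * out.time) + 90.0
        assert np.max(np.abs(out.pressure_mmhg - expected)) < 1e-3

    def test_same_length_uniform_grid_is_identity(self):
        p = np.random.default_rng(0).normal(90, 10, size=128)
        rec = _record(p)
        out = resample_cycle(rec, 128)
        assert np.allclose(out.pressure_mmhg, p, atol=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            WaveformRecord(site="x", time=np.array([0.0, 0.1, 0.2]),
                           pressure_mmhg=np.array([1.0, 2.0, 3.0]))


class TestHarmonicEnergy:
    def test_pure_fundamental_is_all_energy(self):
        t = np.arange(200) / 200
        cyc = ResampledCycle(80 + 10 * np.sin(2 * np.pi * t), period=1.0)
        assert harmonic_energy_fraction(cyc, 1) == pytest.approx(1.0)

    def test_parseval_split_between_harmonics_1_and_6(self):
        t = np.arange(200) / 200
        p = np.sin(2 * np.pi * t) + np.sin(12 * np.pi * t)
        cyc = ResampledCycle(p, period=1.0)
        assert harmonic_energy_fraction(cyc, 5) == pytest.approx(0.5)

    def test_zero_pulsatile_energy_is_an_error(self):
        cyc = ResampledCycle(np.full(100, 80.0), period=1.0)
        with pytest.raises(ValueError, match="undefined"):
            harmonic_energy_fraction(cyc, 5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_in_k_and_reaches_one(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(90, 5, size=64)
        p[0] += 1.0  # guarantee pulsatility
        cyc = ResampledCycle(p, period=1.0)
        fracs = [harmonic_energy_fraction(cyc, k) for k in range(1, 33)]
        assert all(0.0 <= f <= 1.0 + 1e-12 for f in fracs)
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] == pytest.approx(1.0)

    def test_parseval_total_energy(self):
        rng = np.random.default_rng(1)
        p = rng.normal(90, 8, size=128)
        spec = np.fft.rfft(p - p.mean())
        w = np.full(spec.size, 2.0)
        w[0] = 1.0
        w[-1] = 1.0
        total_freq = np.sum(np.abs(spec) ** 2 * w) / 128 ** 2 * 128
        total_time = np.sum((p - p.mean()) ** 2)
        assert total_freq == pytest.approx(total_time, rel=1e-10)


class TestAccuracy:
    def test_identical_cycles_are_accurate(self):
        p = np.linspace(60, 120, 200)
        err, ok = waveform_accuracy(p, p)
        assert err == 0.0 and ok

    @pytest.mark.parametrize("offset,expected_ok", [(0.4, True), (0.6, False)])
    def test_threshold_at_half_mmhg(self, offset, expected_ok):
        p = np.linspace(60, 120, 200)
        err, ok = waveform_accuracy(p + offset, p)
        assert err == pytest.approx(offset)
        assert ok is expected_ok

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            waveform_accuracy(np.zeros(100), np.zeros(99))


class TestFeatures:
    def _two_hump_cycle(self, t_notch=0.36):
        t = np.arange(200) / 200
        p = 75 + 45 * np.exp(-((t - 0.22) / 0.09) ** 2) \
            + 12 * np.exp(-((t - 0.48) / 0.06) ** 2)
        dip = t_notch
        return ResampledCycle(p, period=1.0), t

    def test_notch_in_constructed_fixture(self):
        cyc, t = self._two_hump_cycle()
        f = extract_features(cyc)
        # local minimum between the two Gaussian humps
        expected_notch = t[np.argmin(cyc.pressure_mmhg[50:90]) + 50]
        assert f.notch_found
        assert abs(f.t_notch - expected_notch) <= 1.0 / 200 + 1e-12
        assert f.t_peak == pytest.approx(0.22, abs=0.01)

    def test_monotone_cycle_has_no_notch(self):
        p = np.linspace(120, 60, 200)
        f = extract_features(ResampledCycle(p, period=1.0))
        assert not f.notch_found
        assert f.t_notch is None

    def test_pulse_pressure_definition(self):
        t = np.arange(100) / 100
        p = 70 + 50 * np.clip(np.sin(2 * np.pi * t), 0, None)
        f = extract_features(ResampledCycle(p, period=1.0))
        assert f.pulse_pressure == pytest.approx(50.0, abs=0.1)
        assert f.p_min == pytest.approx(70.0)


class TestPWV:
    def _pulse(self, delay, T=1.0, n=500):
        t = np.arange(n) * T / n
        p = 70 + 40 * np.exp(-((t - 0.1 - delay) / 0.05) ** 2)
        return ResampledCycle(p, period=T)

    def test_known_transit_time(self):
        a = self._pulse(0.0)
        f = self._pulse(0.06)
        pwv = heart_femoral_pwv(a, f, 0.6)
        assert pwv == pytest.approx(10.0, rel=0.05)

    def test_zero_delay_is_an_error(self):
        a = self._pulse(0.0)
        with pytest.raises(ValueError):
            heart_femoral_pwv(a, a, 0.6)

    def test_nonpositive_path_rejected(self):
        a = self._pulse(0.0)
        with pytest.raises(ValueError, match="path length"):
            heart_femoral_pwv(a, self._pulse(0.05), 0.0)

    def test_simulated_uniform_tube_recovers_wave_speed(self):
        """Foot-to-foot PWV in a simulated tube within 5% of c0."""
        from pulsetwin import _kernel
        from pulsetwin.network import single_vessel_network
        from pulsetwin.solver import (SolverConfig, run_prescribed_inflow,
                                      stable_dt)
        c0 = 8.0
        net = single_vessel_network(length=1.6, diameter=0.02, c0=c0,
                                    gamma=0.0, Gamma=0.0, n_elements=320)
        cfg = SolverConfig(cfl=0.5)
        dt = stable_dt(net, cfg)
        steps = int(round(0.30 / dt))
        tt = np.arange(steps) * dt
        qin = 8e-6 * np.exp(-(((tt - 0.04) / 0.012) ** 2))
        t, P, Q, flat, _ = run_prescribed_inflow(
            net, qin, cfg, outlet_kinds={1: _kernel.OUT_ABSORBING})
        rec_a = WaveformRecord(site="a", time=t, pressure_mmhg=P[:, 40] / 133.322)
        rec_b = WaveformRecord(site="b", time=t, pressure_mmhg=P[:, 240] / 133.322)
        pwv = heart_femoral_pwv(rec_a, rec_b, (240 - 40) * net.segments[1].dx)
        assert pwv == pytest.approx(c0, rel=0.05)
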