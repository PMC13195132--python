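"""The generators must actually deliver the statistics they promise —
otherwise every downstream ground-truth comparison is meaningless."""

import numpy as np
import pytest
from scipy import stats

from hippoephys import synthio, spectral
from hippoephys.phaselock import circ_stats, rayleigh_test


class TestGenLfp:
    def test_white_noise_when_exponent_zero(self):
        ts, _ = synthio.gen_lfp(synthio.LfpSpec(
            duration_s=30, rate_hz=1000, aperiodic_exponent=0.0, seed=1))
        spec = spectral.welch(ts, 5.0, 0.5, None)
        sel = spec.freqs_hz > 1
        # flat spectrum: log-log slope ~ 0
        slope = np.polyfit(np.log10(spec.freqs_hz[sel]),
                           np.log10(spec.power[sel]), 1)[0]
        assert abs(slope) < 0.05

    def test_target_loglog_slope(self):
        ts, _ = synthio.gen_lfp(synthio.LfpSpec(
            duration_s=60, rate_hz=2000, aperiodic_exponent=2.0, seed=1))
        spec = spectral.welch(ts, 10.0, 0.5, 0.1)
        sel = (spec.freqs_hz >= 1) & (spec.freqs_hz <= 100)
        slope = np.polyfit(np.log10(spec.freqs_hz[sel]),
                           np.log10(spec.power[sel]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.1)

    def test_oscillation_dominates_residual(self, theta_lfp):
        spec = spectral.welch(theta_lfp, 10.0, 0.5, 0.1)
        fit = spectral.fit_aperiodic(spec)
        sel = (fit.residual.freqs_hz >= 1) & (fit.residual.freqs_hz <= 100)
        peak_f = fit.residual.freqs_hz[sel][np.argmax(fit.residual.power[sel])]
        assert 4.0 <= peak_f <= 12.0

    def test_parseval(self):
        # exponent 0.5 keeps the sub-window (< 1/window) spectral mass that
        # Welch cannot see negligible, so the identity is well-posed
        ts, _ = synthio.gen_lfp(synthio.LfpSpec(
            duration_s=60, rate_hz=2000, aperiodic_exponent=0.5, seed=3))
        spec = spectral.welch(ts, 10.0, 0.5, None)
        assert np.trapezoid(spec.power, spec.freqs_hz) == pytest.approx(
            ts.data.var(), rel=0.05)

    def test_deterministic_per_seed(self):
        spec = synthio.LfpSpec(duration_s=2, seed=7)
        a, _ = synthio.gen_lfp(spec)
        b, _ = synthio.gen_lfp(synthio.LfpSpec(duration_s=2, seed=7))
        np.testing.assert_array_equal(a.data, b.data)

    def test_rejects_super_nyquist_components(self):
        with pytest.raises(ValueError):
            synthio.gen_lfp(synthio.LfpSpec(
                rate_hz=100, oscillations=[(60.0, 1.0, 0.0)]))


class TestGenPsc:
    def test_zero_rate_gives_pure_noise(self):
        ts, gt = synthio.gen_psc_sweep(synthio.PscSweepSpec(
            duration_s=5, event_rate_hz=0.0, noise_sd_pa=2.0,
            drift_pa_per_s=1.0, seed=2))
        assert gt.event_times_s.size == 0
        assert abs(ts.data.std() - 2.0) < 0.5  # noise + mild drift

    def test_degenerate_kappa_pins_phases(self):
        ts, gt = synthio.gen_psc_sweep(synthio.PscSweepSpec(
            duration_s=30, event_rate_hz=5, locking=(8.0, 1e6, 1.0), seed=3))
        assert np.allclose(gt.event_phases_rad, 1.0, atol=0.01)

    def test_vonmises_phase_sample_mean(self):
        spec = synthio.PscSweepSpec(duration_s=100, event_rate_hz=5,
                                    locking=(8.0, 2.0, 0.8), seed=4)
        _, gt = synthio.gen_psc_sweep(spec)
        assert gt.event_times_s.size > 400
        mu, _ = circ_stats(gt.event_phases_rad)
        assert abs(np.degrees(mu - 0.8)) < 5.0

    def test_event_count_follows_rate(self):
        _, gt = synthio.gen_psc_sweep(synthio.PscSweepSpec(
            duration_s=60, event_rate_hz=5, seed=5))
        assert stats.poisson(300).ppf(0.001) <= gt.event_times_s.size <= \
            stats.poisson(300).ppf(0.999)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            synthio.gen_psc_sweep(synthio.PscSweepSpec(event_rate_hz=-1))

    def test_rise_must_be_faster_than_decay(self):
        with pytest.raises(ValueError):
            synthio.gen_psc_sweep(synthio.PscSweepSpec(rise_ms=10, decay_ms=5))


class TestGenSpikes:
    def test_refractory_respected_without_bursts(self):
        spikes, _ = synthio.gen_spike_train(synthio.SpikeTrainSpec(
            duration_s=300, base_rate_hz=10, burst_rate_hz=0,
            refractory_ms=2.0, seed=6))
        assert np.diff(spikes).min() * 1000 >= 2.0

    def test_burst_count_within_poisson_error(self):
        spec = synthio.SpikeTrainSpec(
            duration_s=600, base_rate_hz=1.0, burst_rate_hz=0.1,
            spikes_per_burst_dist=(1.0,), intra_burst_isi_ms=3.0, seed=7)
        _, gt = synthio.gen_spike_train(spec)
        n = len(gt.burst_windows_s)
        assert stats.poisson(60).ppf(0.001) <= n <= stats.poisson(60).ppf(0.999)

    def test_theta_modulation_nonuniform(self):
        spikes, _ = synthio.gen_spike_train(synthio.SpikeTrainSpec(
            duration_s=120, base_rate_hz=5, theta_mod=(8.0, 1.0, 0.0), seed=8))
        phases = np.mod(2 * np.pi * 8.0 * spikes + np.pi, 2 * np.pi) - np.pi
        assert rayleigh_test(phases) < 0.05


class TestSpeedAndCc:
    def test_speed_block_means(self):
        ts, gt = synthio.gen_speed_trace([(5.0, 10.0), (5.0, 0.0)], seed=9)
        assert ts.rate_hz == 50.0
        assert ts.data[:250].mean() == pytest.approx(10.0, abs=0.2)
        assert ts.data[250:].mean() == pytest.approx(0.0, abs=0.2)
        assert gt.state_blocks == [(0.0, 5.0, "run"), (5.0, 10.0, "rest")]

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            synthio.gen_speed_trace([(5.0, -1.0)])

    def test_hyperpolarizing_step_obeys_ohm(self):
        sweeps = synthio.gen_currentclamp_sweeps(
            100.0, -65.0, [-100.0], noise_sd_mv=0.0, seed=0)
        v = sweeps[0].data
        fs = sweeps[0].rate_hz
        v_ss = v[int(0.65 * fs): int(0.69 * fs)].mean()
        assert v_ss - (-65.0) == pytest.approx(-10.0, abs=0.1)

    def test_zero_step_is_flat(self):
        sweeps = synthio.gen_currentclamp_sweeps(
            100.0, -65.0, [0.0], noise_sd_mv=0.0, seed=0)
        assert np.allclose(sweeps[0].data, -65.0)
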