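import numpy as np
import pytest

from hippoephys.core import TimeSeries
from hippoephys import patch, synthio
from hippoephys.scoring import match_events


def sweep_with_kernels(times_s, amps, duration=2.0, rate=20000.0,
                       rise=1.0, decay=8.0, noise=2.0, seed=1):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise, int(duration * rate))
    k = synthio.psc_kernel(rate, rise, decay)
    for t, a in zip(times_s, amps):
        i0 = int(t * rate)
        seg = k[: x.size - i0]
        x[i0: i0 + seg.size] -= a * seg  # inward
    return TimeSeries(x, rate, units="pA")


class TestDetectPsc:
    def test_single_event_amplitude(self):
        ts = sweep_with_kernels([1.0], [20.0])
        evs = patch.detect_psc(ts, patch.EPSC_CONFIG, "inward")
        assert len(evs) == 1
        assert evs[0].amplitude_pa == pytest.approx(20.0, abs=3.0)
        assert abs(evs[0].onset_s - 1.0) < 0.005

    def test_small_event_below_min_amp(self):
        ts = sweep_with_kernels([1.0], [5.0])
        evs = patch.detect_psc(ts, patch.EPSC_CONFIG, "inward")
        assert evs == []

    def test_min_separation_merges_close_pair(self):
        # two kernels 50 samples (2.5 ms) apart with min_separation 200
        ts = sweep_with_kernels([1.0, 1.0025], [20.0, 20.0], noise=1.0)
        evs = patch.detect_psc(ts, patch.EPSC_CONFIG, "inward")
        assert len(evs) == 1

    def test_translation_equivariance(self):
        a = sweep_with_kernels([0.5, 1.2], [20.0, 25.0], noise=1.0, seed=3)
        b = TimeSeries(np.roll(a.data, 4000), a.rate_hz)  # +0.2 s
        ev_a = patch.detect_psc(a, patch.EPSC_CONFIG, "inward")
        ev_b = patch.detect_psc(b, patch.EPSC_CONFIG, "inward")
        assert len(ev_a) == len(ev_b)
        for x, y in zip(ev_a, ev_b):
            assert y.onset_s - x.onset_s == pytest.approx(0.2, abs=0.001)

    def test_min_amp_monotonicity(self):
        ts, _ = synthio.gen_psc_sweep(synthio.PscSweepSpec(duration_s=10, seed=5))
        counts = []
        for amp in (20.0, 10.0, 7.0, 3.0):
            cfg = patch.PscDetectConfig(min_amp_pa=amp)
            counts.append(len(patch.detect_psc(ts, cfg, "inward")))
        assert counts == sorted(counts)

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            patch.detect_psc(TimeSeries(np.empty(0), 20000.0),
                             patch.EPSC_CONFIG, "inward")

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            patch.detect_psc(sweep_with_kernels([1.0], [20.0]),
                             patch.PscDetectConfig(min_amp_pa=-1), "inward")

    def test_default_conditions_recall_precision(self, psc_sweep_default):
        ts, gt = psc_sweep_default
        evs = patch.detect_psc(ts, patch.EPSC_CONFIG, "inward")
        rec, prec, _ = match_events(gt.event_times_s,
                                    [e.onset_s for e in evs], 0.010)
        assert rec > 0.8 and prec > 0.85


class TestKinetics:
    def test_noiseless_decay_tau(self):
        k = 20.0 * synthio.psc_kernel(20000.0, 1.0, 10.0)
        amp, rise, tau = patch.psc_kinetics(k, 20000.0)
        assert amp == pytest.approx(20.0, rel=0.01)
        assert tau == pytest.approx(10.0, abs=0.5)

    def test_rectangular_event_amplitude_exact(self):
        w = np.zeros(200)
        w[50:150] = 7.0
        amp, _, _ = patch.psc_kinetics(w, 20000.0)
        assert amp == 7.0

    def test_noisy_tau_recovery_monte_carlo(self):
        rng = np.random.default_rng(11)
        k = 20.0 * synthio.psc_kernel(20000.0, 1.0, 10.0)
        taus = []
        for _ in range(100):
            w = k + rng.normal(0, 2.0, k.size)
            _, _, tau = patch.psc_kinetics(w, 20000.0)
            if not np.isnan(tau):
                taus.append(tau)
        assert np.mean(taus) == pytest.approx(10.0, abs=1.0)


class TestEventStatsAndCharge:
    def test_frequency_arithmetic(self):
        evs = [patch.PscEvent(t, t + 0.001, 20.0, 5.0, 8.0, "inward")
               for t in np.linspace(0, 29.9, 300)]
        freq, amp, iei = patch.event_stats(evs, 30.0)
        assert freq == pytest.approx(10.0)
        assert iei == pytest.approx(0.1, rel=1e-6)

    def test_no_events(self):
        freq, amp, iei = patch.event_stats([], 30.0)
        assert freq == 0.0 and np.isnan(iei)

    def test_rectangle_charge(self):
        x = np.zeros(20000 * 2)
        x[:20000] = 100.0  # 100 pA for 1 s
        q = patch.charge_transfer(TimeSeries(x, 20000.0))
        assert q == pytest.approx(0.1, rel=1e-3)

    def test_triangle_charge(self):
        tri = np.concatenate([np.linspace(0, 100, 20000),
                              np.linspace(100, 0, 20000)])
        q = patch.charge_transfer(TimeSeries(tri, 20000.0))
        assert q == pytest.approx(0.1, rel=1e-3)

    def test_charge_scales_linearly(self):
        x = np.abs(np.random.default_rng(0).normal(size=5000))
        a = patch.charge_transfer(TimeSeries(x, 20000.0))
        b = patch.charge_transfer(TimeSeries(3 * x, 20000.0))
        assert b == pytest.approx(3 * a, rel=1e-9)

    def test_ei_ratio(self):
        assert patch.ei_ratio(2.0, 2.0) == 1.0
        with pytest.raises(ValueError):
            patch.ei_ratio(1.0, 0.0)


class TestDerivativeOnsets:
    def test_p100_returns_all_extrema(self):
        ts = sweep_with_kernels([0.5, 1.0, 1.5], [20.0] * 3, rate=2000.0,
                                noise=0.5)
        all_on = patch.derivative_onsets(ts, "inward", 100.0)
        sub = patch.derivative_onsets(ts, "inward", 25.0)
        assert sub.size <= all_on.size
        assert set(sub).issubset(set(all_on))

    def test_monotone_ramp_no_extrema(self):
        ts = TimeSeries(np.linspace(0, -100, 2000), 2000.0)
        assert patch.derivative_onsets(ts, "inward", 100.0).size == 0

    def test_top_quartile_hits_ground_truth(self):
        ts, gt = synthio.gen_psc_sweep(synthio.PscSweepSpec(
            duration_s=10, rate_hz=2000.0, event_rate_hz=5, amp_mean_pa=20,
            noise_sd_pa=2, seed=5))
        ons = patch.derivative_onsets(ts, "inward", 25.0)
        assert ons.size > 0
        near = np.mean([np.abs(gt.event_times_s - t).min() < 0.005 for t in ons])
        assert near >= 0.9

    def test_invalid_percentile(self):
        ts = sweep_with_kernels([1.0], [20.0])
        with pytest.raises(ValueError):
            patch.derivative_onsets(ts, "inward", 0.0)
        with pytest.raises(ValueError):
            patch.derivative_onsets(ts, "inward", 101.0)


@pytest.fixture(scope="module")
def report():
    tmpl = synthio.ApTemplate(threshold_mv=-45.0, peak_mv=35.0,
                              half_width_ms=0.8)
    steps = [-100.0, -50.0, 0.0, 250.0, 300.0]
    sweeps = synthio.gen_currentclamp_sweeps(100.0, -65.0, steps, tmpl, seed=1)
    return patch.intrinsic_analysis(sweeps, [(i, 0.2, 0.5) for i in steps])


class TestIntrinsic:
    def test_input_resistance(self, report):
        assert report.rin_mohm == pytest.approx(100.0, abs=2.0)

    def test_half_width_recovery(self, report):
        hw = np.mean([a.half_width_ms for a in report.aps])
        assert hw == pytest.approx(0.8, abs=0.05)

    def test_subthreshold_sweep_yields_zero_aps(self, report):
        fi = dict(report.fi_curve)
        assert fi[-50.0] == 0 and fi[0.0] == 0

    def test_fi_curve_monotone_suprathreshold(self, report):
        fi = dict(report.fi_curve)
        assert fi[300.0] > fi[250.0] > 0

    def test_missing_rin_sweep_flagged(self):
        sweeps = synthio.gen_currentclamp_sweeps(100.0, -65.0, [0.0], seed=1)
        rep = patch.intrinsic_analysis(sweeps, [(0.0, 0.2, 0.5)])
        assert np.isnan(rep.rin_mohm)
        assert rep.flags
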