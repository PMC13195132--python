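import numpy as np
import pytest

from hippoephys.core import TimeSeries
from hippoephys import ripples as rp, synthio, epochs as ep
from hippoephys.scoring import match_windows

BASE = dict(duration_s=60.0, rate_hz=2000.0, aperiodic_offset=-2.0,
            aperiodic_exponent=1.0)


def ripple_lfp(snr, seed=0, rate=0.33):
    spec = synthio.LfpSpec(**BASE)
    amp = synthio.ripple_amplitude_for_snr(spec, snr)
    spec.ripples = synthio.RippleSpec(rate_hz=rate, amplitude=amp)
    spec.seed = seed
    return synthio.gen_lfp(spec)


class TestChannelSelection:
    def test_ripple_channel_found(self):
        spec = synthio.LfpSpec(**BASE, seed=4)
        spec.duration_s = 20.0
        spec.ripples = synthio.RippleSpec(
            rate_hz=1.0, amplitude=synthio.ripple_amplitude_for_snr(spec, 6.0))
        shank_map = {c: 0 for c in range(8)}
        probe, _ = synthio.gen_probe_lfp(spec, 8, shank_map, ripple_channels=[3])
        assert rp.select_pyramidal_channel(probe)[0] == 3

    def test_tie_breaks_to_lowest_index(self):
        x = np.random.default_rng(1).normal(size=4000)
        probe = TimeSeries(np.vstack([x, x, x]), 2000.0,
                           channel_shank={0: 0, 1: 0, 2: 0})
        assert rp.select_pyramidal_channel(probe)[0] == 0

    def test_single_channel_shank(self):
        x = np.random.default_rng(2).normal(size=4000)
        probe = TimeSeries(np.vstack([x, x]), 2000.0,
                           channel_shank={0: 0, 1: 1})
        sel = rp.select_pyramidal_channel(probe)
        assert sel == {0: 0, 1: 1}


class TestDetectSwr:
    def test_high_snr_recall_precision_and_duration(self):
        matched = n_gt = n_det = 0
        durs = []
        for seed in range(3):
            ts, gt = ripple_lfp(4.0, seed=seed)
            evs = rp.detect_swr(ts)
            det = [(e.start_s, e.end_s) for e in evs]
            r, p, pairs = match_windows(gt.ripple_windows_s, det, 0.05)
            matched += len(pairs)
            n_gt += len(gt.ripple_windows_s)
            n_det += len(det)
            durs += [evs[j].duration_ms for _, j in pairs]
        assert matched / n_gt >= 0.9
        assert matched / n_det >= 0.9
        assert abs(np.mean(durs) - 60.0) <= 10.0

    def test_recall_monotone_in_snr(self):
        recalls = []
        for snr in (2.0, 4.0, 8.0):
            ts, gt = ripple_lfp(snr, seed=1)
            r, _, _ = match_windows(
                gt.ripple_windows_s,
                [(e.start_s, e.end_s) for e in rp.detect_swr(ts)], 0.05)
            recalls.append(r)
        assert recalls[0] <= recalls[1] <= recalls[2]

    def test_broadband_transient_rejected(self):
        ts, gt = ripple_lfp(6.0, seed=42)
        rng = np.random.default_rng(1)
        amp = synthio.ripple_amplitude_for_snr(synthio.LfpSpec(**BASE), 6.0)
        centers = [10.0, 30.0, 50.0]
        for s in centers:
            i0 = int(s * ts.rate_hz)
            n = int(0.06 * ts.rate_hz)
            ts.data[i0: i0 + n] += 3 * amp * np.hanning(n) * rng.normal(0, 1, n)
        evs = rp.detect_swr(ts)
        for e in evs:
            mid = (e.start_s + e.end_s) / 2
            assert all(abs(mid - (c + 0.03)) > 0.05 for c in centers)

    def test_short_burst_rejected_by_duration(self):
        ts, _ = synthio.gen_lfp(synthio.LfpSpec(**BASE, seed=7))
        amp = synthio.ripple_amplitude_for_snr(synthio.LfpSpec(**BASE), 8.0)
        i0 = int(30.0 * ts.rate_hz)
        n = int(0.010 * ts.rate_hz)  # 10 ms burst
        t = np.arange(n) / ts.rate_hz
        ts.data[i0: i0 + n] += amp * np.hanning(n) * np.sin(2 * np.pi * 180 * t)
        evs = rp.detect_swr(ts)
        assert all(abs((e.start_s + e.end_s) / 2 - 30.005) > 0.05 for e in evs)

    def test_amplitude_scale_invariance(self):
        ts, _ = ripple_lfp(5.0, seed=9)
        a = rp.detect_swr(ts)
        b = rp.detect_swr(ts.with_data(ts.data * 12.5))
        assert [(e.start_s, e.end_s) for e in a] == [(e.start_s, e.end_s) for e in b]

    def test_threshold_monotonicity(self):
        ts, _ = ripple_lfp(4.0, seed=10)
        n = [len(rp.detect_swr(ts, threshold_sd=k)) for k in (2.0, 3.0, 4.0)]
        assert n[0] >= n[1] >= n[2]

    def test_events_disjoint(self):
        ts, _ = ripple_lfp(4.0, seed=11)
        evs = rp.detect_swr(ts)
        for a, b in zip(evs, evs[1:]):
            assert a.end_s <= b.start_s

    def test_low_rate_rejected(self):
        ts = TimeSeries(np.zeros(1000), 500.0)
        with pytest.raises(ValueError):
            rp.detect_swr(ts)


def fake_ripples(n=20, t0=10.0, spacing=2.0, dur=0.06):
    return [rp.RippleEvent(t0 + k * spacing, t0 + k * spacing + dur,
                           t0 + k * spacing + dur / 2, dur * 1000, 10, 5.0, 8.0)
            for k in range(n)]


class TestSwrModulation:
    def test_peak_firing_unit_single_peaked(self, rng):
        evs = fake_ripples()
        spikes = np.sort(np.concatenate(
            [rng.normal((e.start_s + e.end_s) / 2, 0.004, 10) for e in evs]))
        mod = rp.swr_modulation(spikes, evs, [(0.0, 5.0)])
        assert mod.single_peaked
        assert np.argmax(mod.histogram) in (3, 4)

    def test_homogeneous_unit_rarely_single_peaked(self, rng):
        evs = fake_ripples()
        flags = []
        for _ in range(50):
            spikes = np.sort(rng.uniform(9.0, 55.0, 3000))
            flags.append(rp.swr_modulation(spikes, evs, [(0.0, 5.0)]).single_peaked)
        assert np.mean(flags) <= 0.1

    def test_silent_unit(self):
        mod = rp.swr_modulation(np.empty(0), fake_ripples(), [(0.0, 5.0)])
        assert not mod.single_peaked
        assert mod.histogram.sum() == 0

    def test_baseline_rate_from_controls(self, rng):
        spikes = np.sort(rng.uniform(0.0, 5.0, 100))  # 20 Hz in [0, 5]
        mod = rp.swr_modulation(spikes, fake_ripples(), [(0.0, 5.0)])
        assert mod.baseline_rate_hz == pytest.approx(20.0, abs=0.5)

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError):
            rp.swr_modulation(np.empty(0), fake_ripples(), [])


@pytest.fixture(scope="module")
def theta_setup():
    rate = 1000.0
    t = np.arange(int(40.0 * rate)) / rate
    lfp = TimeSeries(np.cos(2 * np.pi * 8.0 * t), rate)
    segs = [ep.StateSegment(0.0, 40.0, "theta")]
    return lfp, segs


class TestThetaPhasePref:
    def test_spikes_at_troughs(self, theta_setup):
        lfp, segs = theta_setup
        spikes = (np.arange(10, 300) + 0.5) / 8.0  # cosine minima
        pref, p = rp.theta_phase_pref(spikes, segs, lfp)
        assert min(pref, 360 - pref) < 10.0
        assert p < 1e-6

    def test_spikes_at_peaks(self, theta_setup):
        lfp, segs = theta_setup
        spikes = np.arange(10, 300) / 8.0
        pref, _ = rp.theta_phase_pref(spikes, segs, lfp)
        assert pref == pytest.approx(180.0, abs=10.0)

    def test_designed_preference_recovered(self):
        ses = synthio.gen_awake_session(duration_s=60.0, seed=5)
        segs = [ep.StateSegment(0.0, ses.run_until_s, "theta")]
        spikes = synthio.gen_fs_unit_spikes(ses, 270.0, True, seed=5)
        pref, _ = rp.theta_phase_pref(spikes, segs, ses.lfp)
        assert pref == pytest.approx(270.0, abs=10.0)

    def test_too_few_spikes_undefined(self, theta_setup):
        lfp, segs = theta_setup
        pref, p = rp.theta_phase_pref(np.array([1.0, 2.0]), segs, lfp)
        assert np.isnan(pref) and np.isnan(p)


class TestClassifyPvBasket:
    def _mod(self, single, pref):
        return rp.SwrModulation(np.ones(8), 5.0, single,
                                preferred_phase_deg=pref)

    def test_criteria(self):
        assert rp.classify_pv_basket(self._mod(True, 270.0))
        assert not rp.classify_pv_basket(self._mod(True, 100.0))
        assert not rp.classify_pv_basket(self._mod(False, 270.0))
        assert rp.classify_pv_basket(self._mod(True, 203.0))
        assert rp.classify_pv_basket(self._mod(True, 339.0))
        assert not rp.classify_pv_basket(self._mod(True, float("nan")))
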