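import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hippoephys import units


def train_from_isis(isis_ms):
    return np.concatenate([[0.0], np.cumsum(np.asarray(isis_ms) / 1000.0)])


class TestSpikeWidth:
    def test_trough_to_peak_time(self):
        rate = 30000.0
        w = np.zeros(90)
        w[30] = -1.0                      # trough at 1.0 ms
        w[30 + 18] = 0.5                  # after-peak at 1.6 ms
        assert units.spike_width(w, rate) == pytest.approx(0.6)

    def test_narrow_template(self):
        rate = 30000.0
        w = np.zeros(60)
        w[20] = -1.0
        w[29] = 0.4                       # 0.3 ms later
        assert units.spike_width(w, rate) == pytest.approx(0.3)

    def test_reversed_waveform_rejected(self):
        w = np.zeros(60)
        w[20] = 0.5   # peak precedes the trough: malformed
        w[59] = -1.0
        with pytest.raises(ValueError):
            units.spike_width(w, 30000.0)


class TestAcgFirstMoment:
    def test_poisson_train_flat_acg(self, rng):
        t = np.sort(rng.uniform(0, 600, 12000))  # 20 Hz Poisson
        fm, peak = units.acg_first_moment(t)
        assert fm == pytest.approx(25.0, abs=1.0)
        assert peak >= 10

    def test_bursting_train_low_first_moment(self):
        # pairs at 3 ms spacing, pairs far apart
        starts = np.arange(0, 600, 0.5)
        t = np.sort(np.concatenate([starts, starts + 0.003]))
        fm, _ = units.acg_first_moment(t)
        assert fm < 10.0

    def test_sparse_train_low_peak_count(self):
        t = np.array([0.0, 0.01, 5.0, 5.02, 10.0])
        fm, peak = units.acg_first_moment(t)
        assert peak < 10

    def test_too_few_spikes(self):
        with pytest.raises(ValueError):
            units.acg_first_moment(np.array([1.0]))


class TestClassifyUnit:
    @pytest.mark.parametrize("width,fm,expected", [
        (0.6, 20.0, "pyramidal"),
        (0.4, 30.0, "fs_interneuron"),
        (0.6, 30.0, "unclassified"),
        (0.4, 10.0, "unclassified"),
        (0.5, 10.0, "unclassified"),   # boundary width excluded
        (0.5, 30.0, "unclassified"),
        (0.6, 25.0, "unclassified"),   # boundary first moment excluded
        (0.4, 20.0, "unclassified"),
    ])
    def test_criteria(self, width, fm, expected):
        assert units.classify_unit(width, fm) == expected

    def test_grid_matches_truth_table(self):
        widths = np.linspace(0.1, 1.0, 100)
        fms = np.linspace(1.0, 50.0, 100)
        for w in widths:
            for fm in fms:
                got = units.classify_unit(w, fm)
                if w > 0.5 and fm < 25.0:
                    assert got == "pyramidal"
                elif w < 0.5 and fm > 20.0:
                    assert got == "fs_interneuron"
                else:
                    assert got == "unclassified"

    def test_nonfinite_metrics_excluded(self):
        assert units.classify_unit(float("nan"), 20.0) == "excluded"


class TestRateCategory:
    @pytest.mark.parametrize("rate,cls,expected", [
        (0.5, "pyramidal", "low"),
        (3.0, "pyramidal", "medium"),
        (7.0, "pyramidal", "high"),
        (10.0, "fs_interneuron", "low"),
        (30.0, "fs_interneuron", "medium"),
        (45.0, "fs_interneuron", "high"),
        (1.0, "pyramidal", "medium"),   # half-open [low, high)
        (5.0, "pyramidal", "high"),
    ])
    def test_cutpoints(self, rate, cls, expected):
        assert units.rate_category(rate, cls) == expected

    def test_unknown_class(self):
        with pytest.raises(ValueError):
            units.rate_category(1.0, "unclassified")


class TestDetectBursts:
    def test_worked_example(self):
        t = train_from_isis([3, 3, 200, 3, 200])  # 6 spikes
        rep = units.detect_bursts(t, total_time_s=10.0)
        assert len(rep.bursts) == 1
        assert rep.bursts[0][1] == 3
        assert rep.burst_index == pytest.approx(0.5)
        assert rep.burst_event_rate_hz == pytest.approx(0.1)

    def test_pairs_are_not_bursts(self):
        t = train_from_isis([3, 200, 3, 200])
        rep = units.detect_bursts(t, total_time_s=10.0)
        assert rep.bursts == [] and rep.burst_index == 0.0

    def test_maximal_run_is_single_burst(self):
        t = train_from_isis([3, 3, 3, 3])  # 5 spikes
        rep = units.detect_bursts(t, total_time_s=10.0)
        assert len(rep.bursts) == 1
        assert rep.bursts[0][1] == 5
        assert rep.burst_index == 1.0
        assert rep.spikes_per_burst == {5: 1.0}

    def test_monotone_in_isi_threshold(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 60, 2000))
        frac = [units.detect_bursts(t, thr, total_time_s=60.0).burst_index
                for thr in (5.0, 10.0, 15.0)]
        assert frac == sorted(frac)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            units.detect_bursts(np.array([1.0, 0.5]), total_time_s=10.0)

    @given(st.lists(st.floats(min_value=0.5, max_value=500.0),
                    min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_burst_index_bounds(self, isis):
        rep = units.detect_bursts(train_from_isis(isis), total_time_s=1000.0)
        assert 0.0 <= rep.burst_index <= 1.0
        assert (rep.burst_index == 0.0) == (len(rep.bursts) == 0)
        assert all(n >= 3 for _, n, _ in rep.bursts)


class TestIsiDistribution:
    def test_all_fast_isis(self):
        t = train_from_isis([3.0] * 20)
        _, _, cum = units.isi_distribution(t)
        assert cum == 1.0

    def test_all_slow_isis(self):
        t = train_from_isis([50.0] * 20)
        centers, hist, cum = units.isi_distribution(t)
        assert hist.sum() == 0.0 and cum == 0.0

    def test_designed_burst_fraction(self):
        from hippoephys import synthio
        spec = synthio.SpikeTrainSpec(
            duration_s=600, base_rate_hz=1.0, burst_rate_hz=0.2,
            spikes_per_burst_dist=(1.0,), intra_burst_isi_ms=3.0, seed=4)
        spikes, gt = synthio.gen_spike_train(spec)
        _, _, cum = units.isi_distribution(spikes)
        # each 3-spike burst contributes 2 fast ISIs
        expected = 2 * len(gt.burst_windows_s) / (spikes.size - 1)
        assert cum == pytest.approx(expected, abs=0.02)
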