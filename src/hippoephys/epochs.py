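"""Oscillation-episode detection and behavioral-state segmentation.

Oscillation epochs follow the BOSC family of methods with an
aperiodic-model background (the variant usually called fBOSC): Morlet
wavelet power on a log-spaced frequency grid is compared, per frequency,
against the 95th percentile of the chi-square(2) distribution scaled to
the fitted 1/f background's mean power at that frequency; runs of
supra-threshold power lasting at least ``min_cycles`` oscillation cycles
become episodes, merged across in-band frequencies.

State segmentation comes in two flavors: theta/non-theta from the
multitaper theta/delta power ratio combined with treadmill speed, and
running/resting from speed alone. In both cases contiguous segments
shorter than 2 s are discarded (relabelled ambiguous), and samples
meeting neither criterion are ambiguous, so the labels always partition
the timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import fftconvolve
from scipy.signal.windows import dpss
from scipy.stats import chi2

from .core import TimeSeries
from .spectral import AperiodicFit, Spectrum, fit_aperiodic

__all__ = [
    "OscEpoch",
    "StateSegment",
    "BAND_BOUNDS",
    "morlet_power",
    "detect_osc_epochs",
    "theta_state_segments",
    "run_rest_segments",
]

BAND_BOUNDS = {"delta": (1.0, 4.0), "theta": (4.0, 12.0)}


@dataclass
class OscEpoch:
    band: str
    start_s: float
    end_s: float
    n_cycles: float
    mean_freq_hz: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class StateSegment:
    start_s: float
    end_s: float
    label: str  # theta | non_theta | running | resting | ambiguous

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def morlet_power(
    ts: TimeSeries, freqs_hz: np.ndarray, n_cycles: float = 6.0
) -> np.ndarray:
    """Morlet wavelet power, shape (n_freqs, n_samples).

    The wavelet at frequency f has Gaussian envelope SD
    ``n_cycles / (2*pi*f)`` seconds and unit L2 norm, so the power scale
    is common across frequencies.
    """
    x = np.asarray(ts.data, dtype=float)
    out = np.empty((len(freqs_hz), x.size))
    for k, f in enumerate(freqs_hz):
        s = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(4 * s * ts.rate_hz))
        tt = np.arange(-half, half + 1) / ts.rate_hz
        w = np.exp(2j * np.pi * f * tt) * np.exp(-(tt**2) / (2 * s**2))
        w /= np.sqrt(np.sum(np.abs(w) ** 2))
        conv = fftconvolve(x, w, mode="same")
        out[k] = np.abs(conv) ** 2
    return out


def _log_freq_grid(lo: float, hi: float, per_octave: int = 3) -> np.ndarray:
    n = int(np.ceil(np.log2(hi / lo) * per_octave)) + 1
    return lo * 2 ** (np.arange(n) / per_octave)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [mask.size]
    return list(zip(starts, ends))


def _merge_intervals(ivals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    out = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def detect_osc_epochs(
    lfp: TimeSeries,
    band: str | tuple[float, float],
    aperiodic: AperiodicFit | None = None,
    min_cycles: float = 2.0,
    wavelet_cycles: float = 6.0,
    threshold_percentile: float = 95.0,
    fit_range_hz: tuple[float, float] = (1.0, 100.0),
) -> list[OscEpoch]:
    """Detect band-limited oscillation episodes against a 1/f background.

    ``aperiodic`` must be a fit of the *time-averaged wavelet power
    spectrum* (so its units match the thresholded quantity); pass None
    to fit it here. ``band`` is a name ('delta'/'theta') or explicit
    (lo, hi) Hz bounds.
    """
    lo, hi = BAND_BOUNDS[band] if isinstance(band, str) else band
    name = band if isinstance(band, str) else f"{lo:g}-{hi:g}Hz"
    if lo < fit_range_hz[0] or hi > fit_range_hz[1]:
        raise ValueError(f"band [{lo}, {hi}] Hz outside fitted range {fit_range_hz}")
    if hi >= lfp.rate_hz / 2:
        raise ValueError("band exceeds Nyquist")
    grid = _log_freq_grid(*fit_range_hz)
    power = morlet_power(lfp, grid, wavelet_cycles)
    if aperiodic is None:
        aperiodic = fit_aperiodic(
            Spectrum(grid, power.mean(axis=1)), fit_range_hz=fit_range_hz)
    bg_mean = aperiodic.model_linear(grid)
    # wavelet power of a Gaussian process is exponential: chi2(2)-scaled mean
    thresh = bg_mean * chi2.ppf(threshold_percentile / 100.0, 2) / 2.0

    in_band = (grid >= lo) & (grid <= hi)
    episodes: list[tuple[float, float]] = []
    for k in np.flatnonzero(in_band):
        # a supra-threshold run overstates the oscillation's duration by
        # the wavelet's own temporal support (SD sigma_t = cycles/(2*pi*f));
        # compensate by 2 sigma_t so sub-minimum transients are not smeared
        # past the cycle criterion
        min_dur = (min_cycles + wavelet_cycles / np.pi) / grid[k]
        for i0, i1 in _runs(power[k] > thresh[k]):
            if (i1 - i0) / lfp.rate_hz >= min_dur:
                episodes.append((lfp.t0_s + i0 / lfp.rate_hz, lfp.t0_s + i1 / lfp.rate_hz))
    merged = _merge_intervals(episodes)
    # dominant in-band frequency per sample, for epoch mean frequency
    band_power = power[in_band]
    band_freqs = grid[in_band]
    peak_f = band_freqs[np.argmax(band_power, axis=0)]
    out = []
    for s, e in merged:
        i0 = lfp.index_at(s)
        i1 = max(lfp.index_at(e), i0 + 1)
        mf = float(np.clip(np.mean(peak_f[i0:i1]), lo, hi))
        out.append(OscEpoch(band=name, start_s=s, end_s=e,
                            n_cycles=(e - s) * mf, mean_freq_hz=mf))
    return out


def _segments_from_labels(
    labels: np.ndarray, rate_hz: float, t0_s: float, min_segment_s: float
) -> list[StateSegment]:
    """Run-length encode labels, discarding short non-ambiguous runs."""
    lab = labels.copy()
    changed = True
    while changed:  # pruning can merge flanking ambiguous runs
        changed = False
        i = 0
        while i < lab.size:
            j = i
            while j < lab.size and lab[j] == lab[i]:
                j += 1
            if lab[i] != "ambiguous" and (j - i) / rate_hz < min_segment_s:
                lab[i:j] = "ambiguous"
                changed = True
            i = j
    segs = []
    i = 0
    while i < lab.size:
        j = i
        while j < lab.size and lab[j] == lab[i]:
            j += 1
        segs.append(StateSegment(t0_s + i / rate_hz, t0_s + j / rate_hz, str(lab[i])))
        i = j
    return segs


def _multitaper_band_power(
    x: np.ndarray, fs: float, band: tuple[float, float], nw: float = 3.0
) -> float:
    n = x.size
    k = int(2 * nw - 1)
    tapers = dpss(n, nw, Kmax=k)
    nfft = next_fast_len(n)
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    spec = np.fft.rfft(tapers * (x - x.mean()), n=nfft, axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel]))


def theta_state_segments(
    lfp: TimeSeries,
    speed: TimeSeries,
    td_thresh: float = 2.0,
    run_speed: float = 5.0,
    rest_speed: float = 1.0,
    window_s: float = 1.6,
    step_s: float = 0.8,
    nw: float = 3.0,
    theta_hz: tuple[float, float] = (4.0, 12.0),
    delta_hz: tuple[float, float] = (2.0, 4.0),
    min_segment_s: float = 2.0,
) -> list[StateSegment]:
    """Theta / non-theta / ambiguous segmentation.

    Theta/delta (T/D) power ratio from multitaper estimates in sliding
    windows, linearly interpolated to LFP sample times; treadmill speed
    aligned by sample-and-hold. Theta requires T/D > 2 and speed above
    the running threshold; non-theta requires T/D < 2 and speed below
    the resting threshold. Note the 2-4 Hz delta band used here.
    """
    if speed.t0_s > lfp.t0_s or speed.times[-1] + 1 / speed.rate_hz < lfp.times[-1]:
        raise ValueError("speed trace does not cover the LFP")
    x = np.asarray(lfp.data, dtype=float)
    nwin = int(round(window_s * lfp.rate_hz))
    nstep = int(round(step_s * lfp.rate_hz))
    centers, ratios = [], []
    for i0 in range(0, x.size - nwin + 1, nstep):
        seg = x[i0 : i0 + nwin]
        tp = _multitaper_band_power(seg, lfp.rate_hz, theta_hz, nw)
        dp = _multitaper_band_power(seg, lfp.rate_hz, delta_hz, nw)
        centers.append(lfp.t0_s + (i0 + nwin / 2) / lfp.rate_hz)
        ratios.append(tp / dp if dp > 0 else np.inf)
    if not centers:
        raise ValueError("LFP shorter than one analysis window")
    t = lfp.times
    td = np.interp(t, centers, ratios)
    # sample-and-hold: speed sample valid until the next one
    idx = np.clip(((t - speed.t0_s) * speed.rate_hz).astype(int), 0, speed.n_samples - 1)
    v = np.asarray(speed.data, dtype=float)[idx]
    labels = np.full(t.size, "ambiguous", dtype=object)
    labels[(td > td_thresh) & (v > run_speed)] = "theta"
    labels[(td < td_thresh) & (v < rest_speed)] = "non_theta"
    return _segments_from_labels(labels, lfp.rate_hz, lfp.t0_s, min_segment_s)


def run_rest_segments(
    speed: TimeSeries,
    run_speed: float = 5.0,
    rest_speed: float = 1.0,
    min_segment_s: float = 2.0,
) -> list[StateSegment]:
    """Running (>5 cm/s) / resting (<1 cm/s) / ambiguous segmentation."""
    v = np.asarray(speed.data, dtype=float)
    if (v < 0).any():
        raise ValueError("negative speeds in trace")
    labels = np.full(v.size, "ambiguous", dtype=object)
    labels[v > run_speed] = "running"
    labels[v < rest_speed] = "resting"
    return _segments_from_labels(labels, speed.rate_hz, speed.t0_s, min_segment_s)
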