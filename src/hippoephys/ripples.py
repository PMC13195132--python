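"""Sharp-wave-ripple (SWR) analytics and putative PV+ basket-cell
identification.

SWR detection: the pyramidal-layer LFP is band-passed 100-250 Hz
(4th-order zero-phase Butterworth), its squared Hilbert envelope is
smoothed with a Gaussian kernel (sigma = 4 ms), and candidate events are
contiguous runs above mean + 3 SD, extended outward to the nearest
crossings of the mean. Candidates survive if their duration is
15-150 ms and their within-event ripple-band power exceeds 4x the
identically processed 250-400 Hz control-band power (spectral
specificity, rejecting broadband transients).

Putative PV+ basket cells: fast-spiking units whose peri-SWR firing
histogram (8 bins spanning each event, centered on the peak) is
single-peaked in the central bins AND whose theta phase preference,
trough-referenced, lies between 203 and 339 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import filtfilt, find_peaks, firwin, hilbert

from .core import TimeSeries
from .epochs import StateSegment
from .phaselock import circ_stats, rayleigh_test
from .sigprep import bandpass

__all__ = [
    "RippleEvent",
    "SwrModulation",
    "select_pyramidal_channel",
    "detect_swr",
    "sample_control_periods",
    "swr_modulation",
    "theta_phase_pref",
    "classify_pv_basket",
]


@dataclass
class RippleEvent:
    start_s: float
    end_s: float
    peak_s: float
    duration_ms: float
    n_cycles: int
    power_z: float
    specificity_ratio: float


@dataclass
class SwrModulation:
    histogram: np.ndarray  # 8-bin peri-SWR spike counts (summed over events)
    baseline_rate_hz: float
    single_peaked: bool
    preferred_phase_deg: float = math.nan
    theta_rayleigh_p: float = math.nan
    is_pv_basket: bool = False


def _envelope_power(
    lfp: TimeSeries, band: tuple[float, float], smooth_sigma_ms: float
) -> np.ndarray:
    filt = bandpass(lfp, band[0], band[1], order=4, zero_phase=True)
    power = np.abs(hilbert(filt.data)) ** 2
    sigma = smooth_sigma_ms / 1000.0 * lfp.rate_hz
    return gaussian_filter1d(power, sigma, truncate=4.0)


def select_pyramidal_channel(
    lfp: TimeSeries,
    shank_map: dict[int, int] | None = None,
    band: tuple[float, float] = (150.0, 250.0),
) -> dict[int, int]:
    """Per shank, the channel with largest mean ripple-band envelope power.

    Ties resolve to the lowest channel index. Returns {shank: channel}.
    """
    if shank_map is None:
        shank_map = lfp.channel_shank or {c: 0 for c in range(lfp.n_channels)}
    mean_power = {}
    for c in range(lfp.n_channels):
        ch = lfp.channel(c)
        filt = bandpass(ch, band[0], band[1], order=4, zero_phase=True)
        mean_power[c] = float(np.mean(np.abs(hilbert(filt.data)) ** 2))
    out: dict[int, int] = {}
    for shank in sorted(set(shank_map.values())):
        chans = sorted(c for c, s in shank_map.items() if s == shank)
        best = max(chans, key=lambda c: (mean_power[c], -c))
        out[shank] = best
    return out


def detect_swr(
    lfp: TimeSeries,
    ripple_band: tuple[float, float] = (100.0, 250.0),
    control_band: tuple[float, float] = (250.0, 400.0),
    smooth_sigma_ms: float = 4.0,
    threshold_sd: float = 3.0,
    duration_ms: tuple[float, float] = (15.0, 150.0),
    specificity_min: float = 4.0,
) -> list[RippleEvent]:
    """Detect SWRs on one (pyramidal-layer) LFP channel."""
    if lfp.rate_hz / 2 <= control_band[1]:
        raise ValueError(
            f"sampling rate {lfp.rate_hz} Hz too low for the "
            f"{control_band[1]} Hz control band")
    power = _envelope_power(lfp, ripple_band, smooth_sigma_ms)
    ctrl_power = _envelope_power(lfp, control_band, smooth_sigma_ms)
    mu, sd = float(power.mean()), float(power.std())
    above = power > mu + threshold_sd * sd
    above_mean = power > mu
    fs = lfp.rate_hz

    # candidate runs, extended to the nearest mean crossings; the minimum
    # duration also applies to the supra-threshold core, so brief noise
    # crossings cannot be stretched past it by the extension
    core_min = int(duration_ms[0] / 1000.0 * fs)
    bounds: list[tuple[int, int]] = []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [above.size]
    for s, e in zip(starts, ends):
        core = e - s
        while s > 0 and above_mean[s - 1]:
            s -= 1
        while e < above.size and above_mean[e]:
            e += 1
        if bounds and s <= bounds[-1][1]:
            bounds[-1] = (bounds[-1][0], max(bounds[-1][1], e), max(bounds[-1][2], core))
        else:
            bounds.append((s, e, core))
    bounds = [(s, e) for s, e, core in bounds if core >= core_min]

    ripple_filt = bandpass(lfp, ripple_band[0], ripple_band[1]).data
    events: list[RippleEvent] = []
    for s, e in bounds:
        dur_ms = (e - s) / fs * 1000.0
        if not (duration_ms[0] <= dur_ms <= duration_ms[1]):
            continue
        spec_ratio = float(power[s:e].mean() / max(ctrl_power[s:e].mean(), 1e-30))
        if spec_ratio < specificity_min:
            continue
        pk = s + int(np.argmax(power[s:e]))
        n_cycles, _ = find_peaks(ripple_filt[s:e])
        events.append(RippleEvent(
            start_s=lfp.t0_s + s / fs,
            end_s=lfp.t0_s + e / fs,
            peak_s=lfp.t0_s + pk / fs,
            duration_ms=dur_ms,
            n_cycles=int(len(n_cycles)),
            power_z=float((power[pk] - mu) / sd),
            specificity_ratio=spec_ratio,
        ))
    return events


def sample_control_periods(
    available: list[tuple[float, float]],
    durations_s: list[float],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Randomly place one control window per requested duration inside the
    available ('non-theta and non-SWR') intervals."""
    fitting = lambda d: [(s, e) for s, e in available if e - s >= d]
    out: list[tuple[float, float]] = []
    for d in durations_s:
        cand = fitting(d)
        if not cand:
            raise ValueError(f"no control interval of at least {d:.3f} s available")
        lens = np.array([e - s - d for s, e in cand])
        probs = (lens + 1e-9) / (lens + 1e-9).sum()
        s, e = cand[rng.choice(len(cand), p=probs)]
        start = rng.uniform(s, e - d)
        out.append((float(start), float(start + d)))
    return out


def subtract_intervals(
    base: list[tuple[float, float]], remove: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Set-difference of half-open interval lists (both may be unsorted)."""
    out = [list(iv) for iv in sorted(base)]
    for rs, re in sorted(remove):
        nxt = []
        for s, e in out:
            if re <= s or rs >= e:
                nxt.append([s, e])
                continue
            if s < rs:
                nxt.append([s, rs])
            if re < e:
                nxt.append([re, e])
        out = nxt
    return [(s, e) for s, e in out if e - s > 1e-12]


def swr_modulation(
    spike_times_s: np.ndarray,
    ripples: list[RippleEvent],
    control_periods: list[tuple[float, float]],
    n_bins: int = 8,
) -> SwrModulation:
    """Peri-SWR firing histogram and matched-control baseline for one unit.

    Each event is divided into ``n_bins`` equal bins centered on the SWR
    peak (the event midpoint); counts are summed over events. The
    modulation is 'single-peaked' when the histogram has a unique local
    maximum and it falls in the two central bins.
    """
    if not control_periods:
        raise ValueError("no control periods available")
    t = np.asarray(spike_times_s, dtype=float)
    hist = np.zeros(n_bins)
    for ev in ripples:
        edges = np.linspace(ev.start_s, ev.end_s, n_bins + 1)
        c, _ = np.histogram(t, bins=edges)
        hist += c
    ctrl_dur = sum(e - s for s, e in control_periods)
    n_ctrl = sum(int(((t >= s) & (t < e)).sum()) for s, e in control_periods)
    baseline = n_ctrl / ctrl_dur if ctrl_dur > 0 else math.nan

    # unique local maximum located in the two central bins; runs of equal
    # counts are merged into one plateau, and maxima below a quarter of
    # the histogram peak are treated as noise, not peaks
    maxima: list[int] = []
    if hist.any():
        floor = 0.25 * hist.max()
        i = 0
        while i < n_bins:
            j = i
            while j + 1 < n_bins and hist[j + 1] == hist[i]:
                j += 1
            left_ok = i == 0 or hist[i - 1] < hist[i]
            right_ok = j == n_bins - 1 or hist[j + 1] < hist[i]
            if left_ok and right_ok and hist[i] >= floor:
                maxima.append((i + j) // 2)
            i = j + 1
    central = {n_bins // 2 - 1, n_bins // 2}
    single = len(maxima) == 1 and maxima[0] in central
    return SwrModulation(histogram=hist, baseline_rate_hz=float(baseline),
                         single_peaked=bool(single))


def theta_phase_pref(
    spike_times_s: np.ndarray,
    theta_segments: list[StateSegment],
    lfp: TimeSeries,
    theta_band: tuple[float, float] = (4.0, 12.0),
    min_spikes: int = 10,
    bin_deg: float = 18.0,
) -> tuple[float, float]:
    """(preferred theta phase in trough-referenced degrees, Rayleigh p).

    The LFP is FIR band-passed into theta, its Hilbert phase is shifted
    so the theta trough maps to 0/360 degrees, and spikes falling inside
    theta-state segments are binned at ``bin_deg`` resolution. Returns
    (nan, nan) below ``min_spikes`` in-segment spikes.
    """
    numtaps = int(3 * lfp.rate_hz / theta_band[0])
    numtaps += 1 - numtaps % 2  # odd length
    coefs = firwin(numtaps, theta_band, pass_zero=False, fs=lfp.rate_hz)
    filt = filtfilt(coefs, [1.0], np.asarray(lfp.data, dtype=float))
    phase = np.angle(hilbert(filt))
    t = np.asarray(spike_times_s, dtype=float)
    keep = np.zeros(t.size, dtype=bool)
    for seg in theta_segments:
        if seg.label == "theta":
            keep |= (t >= seg.start_s) & (t < seg.end_s)
    t = t[keep]
    if t.size < min_spikes:
        return math.nan, math.nan
    idx = np.clip(((t - lfp.t0_s) * lfp.rate_hz).round().astype(int), 0, phase.size - 1)
    trough_deg = np.degrees(np.mod(phase[idx] + np.pi, 2 * np.pi))
    # bin at bin_deg and use bin centers, as in the phase-histogram analysis
    bins = np.floor(trough_deg / bin_deg)
    binned = np.radians((bins + 0.5) * bin_deg)
    mu, _ = circ_stats(binned)
    pref = float(np.mod(np.degrees(mu), 360.0))
    return pref, rayleigh_test(binned)


def classify_pv_basket(
    mod: SwrModulation, phase_range_deg: tuple[float, float] = (203.0, 339.0)
) -> bool:
    """Single-peaked peri-SWR firing AND theta preference in the PV+ range."""
    if math.isnan(mod.preferred_phase_deg):
        return False
    lo, hi = phase_range_deg
    return bool(mod.single_peaked and lo <= mod.preferred_phase_deg <= hi)
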