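"""Voltage-clamp analytics — spontaneous PSC detection and kinetics,
charge transfer, E/I ratio, derivative-percentile onsets — plus
current-clamp intrinsic-property extraction.

Detection follows a derivative-threshold pipeline: dv/dt peaks above a
standard-deviation threshold nominate candidates, which must then pass an
amplitude minimum, a baseline-proximity test of the event start, a
start/end match test (rejecting summating events), and a minimum
separation. All thresholds are configurable; the defaults are the stated
minima for EPSCs (recorded at -70 mV, inward/negative) and IPSCs
(+10 mV, outward/positive).

Noise on raw 20 kHz traces swamps a single-sample derivative, so the
derivative is taken as the slope of a lightly boxcar-smoothed trace over
a matched span (default 0.5 ms); this is a numerical choice of this
implementation, exposed as ``deriv_smooth_ms``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import TimeSeries

__all__ = [
    "PscEvent",
    "PscDetectConfig",
    "EPSC_CONFIG",
    "IPSC_CONFIG",
    "IntrinsicReport",
    "ApFeatures",
    "detect_psc",
    "psc_kinetics",
    "event_stats",
    "charge_transfer",
    "ei_ratio",
    "derivative_onsets",
    "intrinsic_analysis",
]


@dataclass
class PscEvent:
    onset_s: float
    peak_s: float
    amplitude_pa: float
    rise_rate_pa_per_ms: float
    decay_tau_ms: float
    polarity: str
    accepted: bool = True
    rejection_reason: str = ""


@dataclass
class PscDetectConfig:
    dvdt_sd_thresh: float = 1.8
    min_amp_pa: float = 7.0
    start_sd: float = 1.5
    end_match_pa: float = 10.0
    min_separation_samples: int = 200
    deriv_smooth_ms: float = 0.5
    peak_window_ms: float = 10.0
    end_window_ms: float = 30.0

    def validate(self) -> None:
        for name in ("dvdt_sd_thresh", "min_amp_pa", "start_sd", "end_match_pa",
                     "min_separation_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


EPSC_CONFIG = PscDetectConfig(dvdt_sd_thresh=1.8, min_amp_pa=7.0, start_sd=1.5,
                              end_match_pa=10.0, min_separation_samples=200)
IPSC_CONFIG = PscDetectConfig(dvdt_sd_thresh=1.2, min_amp_pa=15.0, start_sd=0.3,
                              end_match_pa=70.0, min_separation_samples=100)


def _boxcar(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x.astype(float)
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def detect_psc(
    sweep: TimeSeries,
    cfg: PscDetectConfig,
    polarity: str,
    return_all: bool = False,
) -> list[PscEvent]:
    """Detect spontaneous PSCs on a baseline-stable sweep.

    Returns accepted events sorted by onset; with ``return_all`` the
    rejected candidates are included, carrying their rejection reason.
    """
    cfg.validate()
    if sweep.n_samples == 0:
        raise ValueError("empty sweep")
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    fs = sweep.rate_hz
    sign = -1.0 if polarity == "inward" else 1.0
    y = sign * np.asarray(sweep.data, dtype=float)  # events positive-going

    span = max(1, int(round(cfg.deriv_smooth_ms / 1000.0 * fs)))
    ys = _boxcar(y, span)

    def _slope(width: int) -> np.ndarray:
        out = np.zeros_like(ys)
        out[:-width] = (ys[width:] - ys[:-width]) / (width / fs * 1000.0)
        return out

    # sensitive slope for threshold detection; a 2x-wider slope for the
    # onset/peak walks so noise dips do not truncate a rise
    d = _slope(span)
    d_seg = _slope(2 * span)

    thresh = d.mean() + cfg.dvdt_sd_thresh * d.std()
    peak_idx, _ = find_peaks(d, height=thresh)

    # baseline from the (robust) median; the SD for the start-proximity
    # test is the plain SD of the trace, as in "within N standard
    # deviations of baseline" read against the recording itself
    baseline = float(np.median(y))
    noise_sd = float(np.std(y))

    peak_win = int(round(cfg.peak_window_ms / 1000.0 * fs))
    end_win = int(round(cfg.end_window_ms / 1000.0 * fs))
    raw: list[tuple[int, int, float, float]] = []  # onset, peak, amp, dvdt
    for i in peak_idx:
        # onset: walk back to where the smoothed derivative last turned up;
        # peak: end of the positive-derivative run (the rise's end)
        j = i
        while j > 0 and d_seg[max(j - 1 - span, 0)] > 0:
            j -= 1
        onset = j
        pk = i
        stop = min(onset + peak_win, y.size - 1)
        while pk < stop and d_seg[pk] > 0:
            pk += 1
        pk = min(pk + span, y.size - 1)  # d_seg leads the trace by its span
        amp = float(ys[pk] - ys[onset])
        raw.append((onset, pk, amp, float(d[i])))
    # de-duplicate candidates resolving to the same onset (one derivative
    # peak per rise; noise can nominate a rise twice)
    by_onset: dict[int, tuple[int, int, float, float]] = {}
    for cand in raw:
        if cand[0] not in by_onset or cand[2] > by_onset[cand[0]][2]:
            by_onset[cand[0]] = cand
    raw = sorted(by_onset.values())

    candidates: list[PscEvent] = []
    # onsets of candidates that clear the amplitude minimum: only these can
    # truncate the end-match window of the preceding event. Candidates
    # closer than the minimum separation count as the same event, so the
    # truncating onset must also be at least min_separation away.
    big_onsets = np.array([c[0] for c in raw if c[2] >= cfg.min_amp_pa], dtype=int)
    for onset, pk, amp, dvdt in raw:
        # end of this event: before the next distinct rise begins, so a
        # following separate event does not masquerade as summation
        end = min(pk + end_win, y.size - 1)
        nxt = np.searchsorted(big_onsets, max(pk + 1, onset + cfg.min_separation_samples))
        if nxt < big_onsets.size:
            end = min(end, max(int(big_onsets[nxt]) - 1, pk))
        ev = PscEvent(
            onset_s=sweep.t0_s + onset / fs,
            peak_s=sweep.t0_s + pk / fs,
            amplitude_pa=amp,
            rise_rate_pa_per_ms=dvdt,
            decay_tau_ms=math.nan,
            polarity=polarity,
        )
        if amp < cfg.min_amp_pa:
            ev.accepted, ev.rejection_reason = False, "below_min_amplitude"
        elif noise_sd > 0 and abs(ys[onset] - baseline) > cfg.start_sd * noise_sd:
            ev.accepted, ev.rejection_reason = False, "start_off_baseline"
        elif abs(ys[end] - ys[onset]) > cfg.end_match_pa:
            ev.accepted, ev.rejection_reason = False, "end_mismatch"
        candidates.append(ev)

    # minimum-separation pruning among accepted events: on conflict keep
    # the larger amplitude
    min_sep_s = cfg.min_separation_samples / fs
    kept: list[PscEvent] = []
    for ev in candidates:
        if not ev.accepted:
            continue
        if kept and ev.onset_s - kept[-1].onset_s < min_sep_s:
            if ev.amplitude_pa > kept[-1].amplitude_pa:
                kept[-1].accepted = False
                kept[-1].rejection_reason = "too_close_smaller"
                kept[-1] = ev
            else:
                ev.accepted = False
                ev.rejection_reason = "too_close_smaller"
        else:
            kept.append(ev)

    # kinetics on accepted events
    for ev in kept:
        i0 = sweep.index_at(ev.onset_s)
        i1 = min(sweep.index_at(ev.peak_s) + end_win, y.size)
        amp, rise, tau = psc_kinetics(ys[i0:i1] - ys[i0], fs)
        ev.decay_tau_ms = tau
        if not math.isnan(rise):
            ev.rise_rate_pa_per_ms = rise
    if return_all:
        return sorted(candidates, key=lambda e: e.onset_s)
    return kept


def psc_kinetics(
    waveform: np.ndarray, rate_hz: float
) -> tuple[float, float, float]:
    """(amplitude, 20-80% rise rate pA/ms, decay tau ms) of one event.

    The waveform is positive-going from its local baseline (index 0).
    Decay tau comes from a single-exponential fit to the segment bounded
    by the 80% and 20% crossings after the peak; a segment too short or
    non-monotone enough to break the fit yields ``nan``.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size < 5:
        return math.nan, math.nan, math.nan
    pk = int(np.argmax(w))
    amp = float(w[pk])
    if amp <= 0:
        return math.nan, math.nan, math.nan

    # rise rate: slope between the 20% and 80% crossings before the peak
    rise = math.nan
    pre = w[: pk + 1]
    above20 = np.flatnonzero(pre >= 0.2 * amp)
    above80 = np.flatnonzero(pre >= 0.8 * amp)
    if above20.size and above80.size and above80[0] > above20[0]:
        dt_ms = (above80[0] - above20[0]) / rate_hz * 1000.0
        rise = 0.6 * amp / dt_ms

    # decay fit on the 80% -> 20% segment after the peak
    post = w[pk:]
    below80 = np.flatnonzero(post <= 0.8 * amp)
    below20 = np.flatnonzero(post <= 0.2 * amp)
    if not below80.size or not below20.size:
        return amp, rise, math.nan
    i80, i20 = below80[0], below20[0]
    if i20 - i80 < 5:
        return amp, rise, math.nan
    seg = post[i80 : i20 + 1]
    t = np.arange(seg.size) / rate_hz * 1000.0  # ms
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau), t, seg,
            p0=[seg[0], max((t[-1] - t[0]) / 1.4, 0.5)],
            bounds=([0, 1e-3], [np.inf, 1e4]), maxfev=2000,
        )
        tau = float(popt[1])
    except RuntimeError:
        tau = math.nan
    return amp, rise, tau


def event_stats(
    events: list[PscEvent], sweep_duration_s: float
) -> tuple[float, float, float]:
    """(frequency_hz, mean_amplitude_pa, mean_iei_s); IEI nan below 2 events."""
    if sweep_duration_s <= 0:
        raise ValueError("duration must be positive")
    n = len(events)
    freq = n / sweep_duration_s
    mean_amp = float(np.mean([e.amplitude_pa for e in events])) if n else math.nan
    if n >= 2:
        onsets = np.sort([e.onset_s for e in events])
        mean_iei = float(np.mean(np.diff(onsets)))
    else:
        mean_iei = math.nan
    return freq, mean_amp, mean_iei


def charge_transfer(sweep: TimeSeries) -> float:
    """Charge in nA*s: trapezoidal integral of |deflection| over the sweep.

    The sweep must be baseline-normalized to 0 (see
    :func:`hippoephys.sigprep.demean_sweep`) and in pA.
    """
    t = sweep.times
    return float(np.trapezoid(np.abs(sweep.data), t)) / 1000.0


def ei_ratio(q_exc: float, q_inh: float) -> float:
    if q_inh == 0:
        raise ValueError("inhibitory charge is zero; E/I undefined")
    return q_exc / q_inh


def derivative_onsets(
    sweep: TimeSeries,
    polarity: str,
    percentile: float,
    smooth_ms: float = 2.5,
    floor_sd: float | None = 1.8,
    return_strengths: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Onset times from the largest derivative extrema.

    The sweep (at the 2 kHz analysis rate) is boxcar-smoothed with a
    2.5 ms window and differentiated; EPSC onsets are derivative minima,
    IPSC onsets derivative maxima. Extrema below ``floor_sd`` standard
    deviations of the derivative trace are discarded (the same
    convention as event detection; pass None to keep every extremum),
    then only extrema whose magnitude lies in the top ``percentile``
    percent of the remaining magnitudes are kept.
    """
    if not (0 < percentile <= 100):
        raise ValueError("percentile must lie in (0, 100]")
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    n = max(1, int(round(smooth_ms / 1000.0 * sweep.rate_hz)))
    ys = _boxcar(np.asarray(sweep.data, dtype=float), n)
    d = np.gradient(ys) * sweep.rate_hz / 1000.0  # pA/ms
    sgn = -d if polarity == "inward" else d
    idx, _ = find_peaks(sgn)
    idx = idx[sgn[idx] > 0]  # extremum of the correct sign
    if idx.size and floor_sd is not None:
        idx = idx[sgn[idx] > sgn.mean() + floor_sd * sgn.std()]
    if idx.size == 0:
        out = np.empty(0)
        return (out, out.copy()) if return_strengths else out
    mags = sgn[idx]
    if percentile < 100:
        cutoff = np.percentile(mags, 100 - percentile)
        keep = mags >= cutoff
        idx, mags = idx[keep], mags[keep]
    times = sweep.t0_s + idx / sweep.rate_hz
    return (times, mags) if return_strengths else times


@dataclass
class ApFeatures:
    time_s: float
    threshold_mv: float
    peak_mv: float
    amplitude_mv: float
    max_dvdt_mv_per_ms: float
    half_width_ms: float
    width_at_threshold_ms: float


@dataclass
class IntrinsicReport:
    vm_mv: float
    rin_mohm: float  # nan if the -100 pA sweep is absent
    aps: list[ApFeatures] = field(default_factory=list)
    fi_curve: list[tuple[float, int]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _width_at(v: np.ndarray, level: float, i_peak: float, fs: float) -> float:
    """Interpolated width (ms) of the spike at a voltage level."""
    above = v >= level
    if not above.any():
        return math.nan
    i_pk = int(i_peak)
    left = i_pk
    while left > 0 and above[left - 1]:
        left -= 1
    right = i_pk
    while right < v.size - 1 and above[right + 1]:
        right += 1
    # linear interpolation at the crossings
    tl = left - (v[left] - level) / (v[left] - v[left - 1]) if left > 0 and v[left] != v[left - 1] else left
    tr = right + (v[right] - level) / (v[right] - v[right + 1]) if right < v.size - 1 and v[right] != v[right + 1] else right
    return (tr - tl) / fs * 1000.0


def detect_aps(
    sweep: TimeSeries,
    dvdt_thresh_mv_per_ms: float = 20.0,
    min_amp_mv: float = 20.0,
) -> list[ApFeatures]:
    """Action potentials by dv/dt crossing plus amplitude criterion."""
    v = np.asarray(sweep.data, dtype=float)
    fs = sweep.rate_hz
    dvdt = np.gradient(v) * fs / 1000.0
    above = dvdt >= dvdt_thresh_mv_per_ms
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    aps: list[ApFeatures] = []
    win = int(0.005 * fs)  # 5 ms search for the peak
    last_peak = -np.inf
    for c in crossings:
        pk = c + int(np.argmax(v[c : c + win]))
        if pk / fs == last_peak:
            continue
        thr = float(v[c])
        peak = float(v[pk])
        amp = peak - thr
        if amp < min_amp_mv:
            continue
        lo = max(0, pk - win)
        hi = min(v.size, pk + win)
        seg = v[lo:hi]
        half = _width_at(seg, thr + amp / 2.0, pk - lo, fs)
        wthr = _width_at(seg, thr, pk - lo, fs)
        aps.append(ApFeatures(
            time_s=sweep.t0_s + pk / fs, threshold_mv=thr, peak_mv=peak,
            amplitude_mv=amp,
            max_dvdt_mv_per_ms=float(dvdt[c : c + win].max()),
            half_width_ms=half, width_at_threshold_ms=wthr,
        ))
        last_peak = pk / fs
    return aps


def intrinsic_analysis(
    sweeps: list[TimeSeries],
    step_protocol: list[tuple[float, float, float]],
    dvdt_thresh_mv_per_ms: float = 20.0,
    min_amp_mv: float = 20.0,
) -> IntrinsicReport:
    """Passive and active properties from a current-step protocol.

    ``step_protocol`` gives, per sweep, (injected_current_pa,
    step_start_s, step_duration_s). Input resistance comes from the
    -100 pA sweep: steady-state deflection at the end of the step over
    the injected current. The F-I curve counts APs per sweep.
    """
    if len(sweeps) != len(step_protocol):
        raise ValueError("one protocol entry per sweep required")
    report = IntrinsicReport(vm_mv=math.nan, rin_mohm=math.nan)
    fs = sweeps[0].rate_hz if sweeps else 0.0
    vms = []
    for ts, (i_pa, t_on, dur) in zip(sweeps, step_protocol):
        pre = ts.data[: ts.index_at(t_on)]
        if pre.size:
            vms.append(float(np.mean(pre[-int(0.05 * fs):])))
    if vms:
        report.vm_mv = float(np.mean(vms))
    for ts, (i_pa, t_on, dur) in zip(sweeps, step_protocol):
        aps = detect_aps(ts, dvdt_thresh_mv_per_ms, min_amp_mv) if i_pa > 0 else []
        # count only APs inside the step window
        aps = [a for a in aps if t_on <= a.time_s < t_on + dur]
        report.aps.extend(aps)
        report.fi_curve.append((i_pa, len(aps)))
        if i_pa == -100.0:
            i_on, i_off = ts.index_at(t_on), ts.index_at(t_on + dur)
            v_pre = float(np.mean(ts.data[max(0, i_on - int(0.05 * fs)) : i_on]))
            v_ss = float(np.mean(ts.data[i_off - int(0.1 * fs) : i_off]))
            report.rin_mohm = (v_ss - v_pre) / i_pa * 1000.0  # mV/pA -> MOhm
    if math.isnan(report.rin_mohm):
        report.flags.append("rin_unavailable_no_-100pA_sweep")
    return report
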