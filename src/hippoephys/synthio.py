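"""Synthetic electrophysiology with known ground truth.

Every generator here emulates one class of signal the analysis stages
consume — LFP with a 1/f^chi aperiodic background plus band-limited
oscillations and ripple transients, voltage-clamp sweeps carrying
biexponential postsynaptic-current (PSC) kernels, sorted spike trains with
parameterized bursts and theta-rate modulation, treadmill speed traces,
and stepwise current-clamp sweeps — and returns the ground truth its
matched detector is scored against (event times and phases, ripple
windows, burst windows, state blocks).

Design notes:

* the aperiodic background is synthesized by exact spectral shaping of
  white-phase noise, so the generated one-sided PSD equals
  ``10**offset / f**exponent`` up to sampling variability;
* oscillations are amplitude-stable cosines with optional spectral
  broadening via slow random phase diffusion; with zero bandwidth the
  component is exactly ``A*cos(2*pi*f*t)``, whose Hilbert phase matches
  the cosine convention used by the phase-locking module;
* all randomness flows through an explicit integer seed; fixed seed means
  bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .core import TimeSeries

__all__ = [
    "LfpSpec",
    "RippleSpec",
    "PscSweepSpec",
    "SpikeTrainSpec",
    "ApTemplate",
    "GroundTruth",
    "gen_lfp",
    "gen_probe_lfp",
    "gen_psc_sweep",
    "gen_spike_train",
    "gen_speed_trace",
    "gen_currentclamp_sweeps",
    "sample_von_mises",
]


@dataclass
class GroundTruth:
    """What a generator promises about its output."""

    event_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_phases_rad: np.ndarray = field(default_factory=lambda: np.empty(0))
    ripple_windows_s: list[tuple[float, float]] = field(default_factory=list)
    burst_windows_s: list[tuple[float, float]] = field(default_factory=list)
    state_blocks: list[tuple[float, float, str]] = field(default_factory=list)


@dataclass
class RippleSpec:
    """Transient high-frequency oscillation bursts injected into an LFP."""

    rate_hz: float = 0.33
    freq_hz: float = 180.0
    duration_ms: float = 60.0
    amplitude: float = 1.0


@dataclass
class LfpSpec:
    duration_s: float = 60.0
    rate_hz: float = 2000.0
    aperiodic_offset: float = 0.0
    aperiodic_exponent: float = 1.0
    # (center_freq_hz, amplitude, bandwidth_hz)
    oscillations: list[tuple[float, float, float]] = field(default_factory=list)
    # (freq_hz, amplitude)
    mains_components: list[tuple[float, float]] = field(default_factory=list)
    ripples: RippleSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic exponent must be >= 0")
        nyq = self.rate_hz / 2.0
        for f, _, _ in self.oscillations:
            if f >= nyq:
                raise ValueError(f"oscillation at {f} Hz exceeds Nyquist {nyq} Hz")
        for f, _ in self.mains_components:
            if f >= nyq:
                raise ValueError(f"mains component at {f} Hz exceeds Nyquist {nyq} Hz")
        if self.ripples is not None and self.ripples.freq_hz >= nyq:
            raise ValueError("ripple frequency exceeds Nyquist")


def _aperiodic_noise(
    n: int, rate_hz: float, offset: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Time series whose one-sided PSD is 10**offset / f**exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    mag = np.zeros_like(freqs)
    nz = freqs > 0
    psd = 10.0**offset / freqs[nz] ** exponent
    # one-sided density P(f) = 2|X|^2 / (fs * n)  =>  |X| = sqrt(P fs n / 2)
    mag[nz] = np.sqrt(psd * rate_hz * n / 2.0)
    phase = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = mag * np.exp(1j * phase)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = mag[-1]  # Nyquist bin must be real
    return np.fft.irfft(spec, n=n)


def _oscillation(
    t: np.ndarray,
    freq_hz: float,
    amp: float,
    bandwidth_hz: float,
    rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if bandwidth_hz > 0:
        # Wiener phase diffusion: Lorentzian line of FWHM ~ bandwidth
        step_sd = np.sqrt(2 * np.pi * bandwidth_hz / rate_hz)
        dphi = rng.normal(0.0, step_sd, size=t.size)
        dphi[0] = 0.0
        phi = np.cumsum(dphi)
    else:
        phi = 0.0
    return amp * np.cos(2 * np.pi * freq_hz * t + phi)


def _ripple_burst(n: int, rate_hz: float, freq_hz: float, amp: float) -> np.ndarray:
    t = np.arange(n) / rate_hz
    return amp * np.hanning(n) * np.sin(2 * np.pi * freq_hz * t)


def gen_lfp(spec: LfpSpec) -> tuple[TimeSeries, GroundTruth]:
    """Generate a single-channel LFP per the spec; see module docstring."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz
    x = _aperiodic_noise(n, spec.rate_hz, spec.aperiodic_offset, spec.aperiodic_exponent, rng)
    for f, a, bw in spec.oscillations:
        x = x + _oscillation(t, f, a, bw, spec.rate_hz, rng)
    for f, a in spec.mains_components:
        x = x + a * np.sin(2 * np.pi * f * t)
    gt = GroundTruth()
    if spec.ripples is not None:
        rs = spec.ripples
        n_rip = rng.poisson(rs.rate_hz * spec.duration_s)
        dur_s = rs.duration_ms / 1000.0
        n_samp = int(round(dur_s * spec.rate_hz))
        starts = np.sort(rng.uniform(0, spec.duration_s - dur_s, size=n_rip))
        # enforce non-overlap with a 100 ms guard so scoring is unambiguous
        kept: list[float] = []
        for s in starts:
            if not kept or s - kept[-1] > dur_s + 0.1:
                kept.append(float(s))
        for s in kept:
            i0 = int(round(s * spec.rate_hz))
            x[i0 : i0 + n_samp] += _ripple_burst(n_samp, spec.rate_hz, rs.freq_hz, rs.amplitude)
            gt.ripple_windows_s.append((s, s + dur_s))
    return TimeSeries(x, spec.rate_hz, units="mV"), gt


def gen_probe_lfp(
    spec: LfpSpec,
    n_channels: int,
    shank_map: dict[int, int],
    ripple_channels: list[int] | None = None,
) -> tuple[TimeSeries, GroundTruth]:
    """Multichannel probe emulation.

    Channels share nothing but their statistics; ripple transients (from
    ``spec.ripples``) are injected only on ``ripple_channels``, one per
    shank, emulating the pyramidal-layer channel.
    """
    spec.validate()
    if ripple_channels is None:
        ripple_channels = []
    chans = []
    gt = GroundTruth()
    for c in range(n_channels):
        sub = LfpSpec(
            duration_s=spec.duration_s,
            rate_hz=spec.rate_hz,
            aperiodic_offset=spec.aperiodic_offset,
            aperiodic_exponent=spec.aperiodic_exponent,
            oscillations=spec.oscillations,
            mains_components=spec.mains_components,
            ripples=spec.ripples if c in ripple_channels else None,
            seed=spec.seed * 1000 + c,
        )
        ts_c, gt_c = gen_lfp(sub)
        chans.append(ts_c.data)
        if c in ripple_channels and not gt.ripple_windows_s:
            gt.ripple_windows_s = gt_c.ripple_windows_s
    return (
        TimeSeries(np.vstack(chans), spec.rate_hz, units="mV", channel_shank=dict(shank_map)),
        gt,
    )


def ripple_amplitude_for_snr(
    spec: LfpSpec, snr: float, band: tuple[float, float] = (100.0, 250.0)
) -> float:
    """Ripple amplitude giving the requested envelope SNR.

    SNR is defined as the ripple's peak band-limited envelope divided by
    the RMS envelope of the aperiodic background within the band; the
    background band variance follows from the analytic PSD.
    """
    lo, hi = band
    chi = spec.aperiodic_exponent
    if abs(chi - 1.0) < 1e-12:
        var = 10.0**spec.aperiodic_offset * np.log(hi / lo)
    else:
        var = 10.0**spec.aperiodic_offset * (hi ** (1 - chi) - lo ** (1 - chi)) / (1 - chi)
    return float(snr * np.sqrt(2.0 * var))


def sample_von_mises(
    mu: float, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Von Mises angles in [-pi, pi); kappa=0 degrades to uniform."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0:
        return rng.uniform(-np.pi, np.pi, size=n)
    raw = rng.vonmises(mu, kappa, size=n)
    return np.mod(raw + np.pi, 2 * np.pi) - np.pi


@dataclass
class PscSweepSpec:
    duration_s: float = 30.0
    rate_hz: float = 20000.0
    polarity: str = "inward"  # inward (EPSC, negative) / outward (IPSC, positive)
    event_rate_hz: float = 5.0
    amp_mean_pa: float = 20.0
    amp_sd_pa: float = 2.0
    rise_ms: float = 1.0
    decay_ms: float = 8.0
    noise_sd_pa: float = 2.0
    drift_pa_per_s: float = 0.0
    # (carrier_freq_hz, vonmises_kappa, preferred_phase_rad)
    locking: tuple[float, float, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be >= 0")
        if self.rise_ms >= self.decay_ms:
            raise ValueError("rise_ms must be < decay_ms")
        if self.amp_mean_pa <= 0:
            raise ValueError("amp_mean_pa must be positive")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")
        if self.locking is not None and self.locking[1] < 0:
            raise ValueError("kappa must be >= 0")


def psc_kernel(rate_hz: float, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Biexponential kernel exp(-t/tau_d) - exp(-t/tau_r), unit peak."""
    tau_r = rise_ms / 1000.0
    tau_d = decay_ms / 1000.0
    t = np.arange(0, 8 * tau_d, 1.0 / rate_hz)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return k / k.max()


def _locked_event_times(
    spec: PscSweepSpec, carrier: TimeSeries | None, n_events: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    freq, kappa, mu = spec.locking  # type: ignore[misc]
    phases = sample_von_mises(mu, kappa, n_events, rng)
    if carrier is not None:
        # invert the carrier's (monotonized) unwrapped Hilbert phase
        phi = np.unwrap(np.angle(hilbert(carrier.data)))
        phi = np.maximum.accumulate(phi)
        lo, hi = phi[0], phi[-1]
        k_min = int(np.ceil((lo + np.pi) / (2 * np.pi)))
        k_max = int(np.floor((hi - np.pi) / (2 * np.pi)))
        cycles = rng.integers(k_min, k_max + 1, size=n_events)
        target = cycles * 2 * np.pi + phases
        times = np.interp(target, phi, carrier.times)
    else:
        n_cycles = int(np.floor(spec.duration_s * freq))
        cycles = rng.integers(0, n_cycles, size=n_events)
        # pure-cosine carrier: phase(t) = 2*pi*f*t
        times = (cycles + np.mod(phases, 2 * np.pi) / (2 * np.pi)) / freq
    order = np.argsort(times)
    return times[order], phases[order]


def gen_psc_sweep(
    spec: PscSweepSpec, carrier: TimeSeries | None = None
) -> tuple[TimeSeries, GroundTruth]:
    """Voltage-clamp sweep with PSC kernels at Poisson or phase-locked times.

    When ``spec.locking`` is set, event times are drawn so that their
    phase on the carrier (Hilbert convention, 0 = cosine peak) follows a
    von Mises law; otherwise times are homogeneous Poisson.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz
    n_events = rng.poisson(spec.event_rate_hz * spec.duration_s)
    if n_events > 0 and spec.locking is not None:
        times, phases = _locked_event_times(spec, carrier, n_events, rng)
    elif n_events > 0:
        times = np.sort(rng.uniform(0, spec.duration_s, size=n_events))
        phases = np.empty(0)
    else:
        times = np.empty(0)
        phases = np.empty(0)
    sign = -1.0 if spec.polarity == "inward" else 1.0
    x = rng.normal(0.0, spec.noise_sd_pa, size=n) + spec.drift_pa_per_s * t
    kern = psc_kernel(spec.rate_hz, spec.rise_ms, spec.decay_ms)
    amps = np.maximum(rng.normal(spec.amp_mean_pa, spec.amp_sd_pa, size=times.size), 1.0)
    for et, a in zip(times, amps):
        i0 = int(round(et * spec.rate_hz))
        seg = kern[: n - i0]
        if seg.size > 0:
            x[i0 : i0 + seg.size] += sign * a * seg
    gt = GroundTruth(event_times_s=times, event_phases_rad=phases)
    return TimeSeries(x, spec.rate_hz, units="pA"), gt


@dataclass
class SpikeTrainSpec:
    duration_s: float = 600.0
    base_rate_hz: float = 2.0
    burst_rate_hz: float = 0.0
    # probability over {3, 4, 5, ...} spikes per burst
    spikes_per_burst_dist: tuple[float, ...] = (1.0,)
    intra_burst_isi_ms: float = 3.0
    # (freq_hz, mod_depth, preferred_phase_rad)
    theta_mod: tuple[float, float, float] | None = None
    refractory_ms: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        if self.base_rate_hz < 0 or self.burst_rate_hz < 0:
            raise ValueError("rates must be >= 0")
        p = np.asarray(self.spikes_per_burst_dist, dtype=float)
        if p.size == 0 or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("spikes_per_burst_dist must be a probability vector")
        if self.theta_mod is not None and not (0 <= self.theta_mod[1] <= 1):
            raise ValueError("mod_depth must lie in [0, 1]")


def gen_spike_train(spec: SpikeTrainSpec) -> tuple[np.ndarray, GroundTruth]:
    """Spike train = refractory Poisson background + parameterized bursts.

    Theta modulation makes the background an inhomogeneous Poisson process
    with rate ``base*(1 + depth*cos(2*pi*f*t - pref))``, sampled by
    thinning; the reference oscillation is ``cos(2*pi*f*t)`` so the
    preferred phase is recoverable by the phase-locking module.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    refr = spec.refractory_ms / 1000.0
    # background
    if spec.theta_mod is not None:
        f, depth, pref = spec.theta_mod
        lam_max = spec.base_rate_hz * (1 + depth)
        n_cand = rng.poisson(lam_max * spec.duration_s)
        cand = np.sort(rng.uniform(0, spec.duration_s, size=n_cand))
        lam = spec.base_rate_hz * (1 + depth * np.cos(2 * np.pi * f * cand - pref))
        keep = rng.uniform(0, lam_max, size=n_cand) < lam
        bg = cand[keep]
    else:
        n_bg = rng.poisson(spec.base_rate_hz * spec.duration_s)
        bg = np.sort(rng.uniform(0, spec.duration_s, size=n_bg))
    if bg.size > 1:  # enforce refractoriness by thinning close followers
        keep_idx = [0]
        for i in range(1, bg.size):
            if bg[i] - bg[keep_idx[-1]] >= refr:
                keep_idx.append(i)
        bg = bg[keep_idx]
    # bursts
    gt = GroundTruth()
    burst_spikes: list[float] = []
    if spec.burst_rate_hz > 0:
        n_b = rng.poisson(spec.burst_rate_hz * spec.duration_s)
        starts = np.sort(rng.uniform(0, spec.duration_s, size=n_b))
        p = np.asarray(spec.spikes_per_burst_dist, dtype=float)
        isi = spec.intra_burst_isi_ms / 1000.0
        last_end = -np.inf
        for s in starts:
            n_spk = 3 + int(rng.choice(p.size, p=p))
            end = s + (n_spk - 1) * isi
            if s - last_end < 0.05 or end > spec.duration_s:  # 50 ms guard
                continue
            burst_spikes.extend(s + np.arange(n_spk) * isi)
            gt.burst_windows_s.append((float(s), float(end)))
            last_end = end
        # drop background spikes falling inside a burst's guard zone
        if gt.burst_windows_s:
            mask = np.ones(bg.size, dtype=bool)
            for s, e in gt.burst_windows_s:
                mask &= ~((bg > s - 0.05) & (bg < e + 0.05))
            bg = bg[mask]
    spikes = np.sort(np.concatenate([bg, np.asarray(burst_spikes)]))
    gt.event_times_s = spikes
    return spikes, gt


def gen_speed_trace(
    blocks: list[tuple[float, float]],
    rate_hz: float = 50.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[TimeSeries, GroundTruth]:
    """Block-structured treadmill speed trace at 50 samples/s.

    Blocks are (duration_s, mean_speed_cm_s); negative speeds are
    rejected; noise is clipped at zero so the trace stays physical.
    """
    if not blocks:
        raise ValueError("need at least one block")
    rng = np.random.default_rng(seed)
    segs = []
    gt = GroundTruth()
    t0 = 0.0
    for dur, mean in blocks:
        if mean < 0:
            raise ValueError("negative speed requested")
        n = int(round(dur * rate_hz))
        segs.append(np.clip(rng.normal(mean, noise_sd, size=n), 0.0, None))
        label = "run" if mean > 5 else ("rest" if mean < 1 else "ambiguous")
        gt.state_blocks.append((t0, t0 + dur, label))
        t0 += dur
    return TimeSeries(np.concatenate(segs), rate_hz, units="cm/s"), gt


@dataclass
class AwakeSession:
    """A synthetic awake recording: LFP with a theta (running) half and a
    ripple-bearing rest half, plus the matching speed trace."""

    lfp: TimeSeries
    speed: TimeSeries
    ripple_windows_s: list[tuple[float, float]]
    theta_freq_hz: float
    run_until_s: float


def gen_awake_session(
    duration_s: float = 120.0,
    rate_hz: float = 1000.0,
    theta_freq_hz: float = 8.0,
    theta_amp: float = 1.0,
    ripple_rate_hz: float = 0.4,
    ripple_snr: float = 6.0,
    seed: int = 0,
) -> AwakeSession:
    """Two-state awake session: first half running with strong theta,
    second half resting with injected sharp-wave ripples.

    The theta oscillation is a pure cosine (zero bandwidth), so its
    Hilbert phase is exactly ``2*pi*f*t`` and units can be given exact
    phase preferences.
    """
    half = duration_s / 2.0
    base = LfpSpec(duration_s=duration_s, rate_hz=rate_hz,
                   aperiodic_offset=-2.0, aperiodic_exponent=1.0, seed=seed)
    amp = ripple_amplitude_for_snr(base, ripple_snr)
    ts, _ = gen_lfp(base)
    t = ts.times
    ts.data[t < half] += theta_amp * np.cos(2 * np.pi * theta_freq_hz * t[t < half])
    # inject ripples only into the rest half, with a non-overlap guard
    rng = np.random.default_rng(seed + 2)
    rs = RippleSpec(rate_hz=ripple_rate_hz, amplitude=amp)
    dur_s = rs.duration_ms / 1000.0
    n_samp = int(round(dur_s * rate_hz))
    n_rip = rng.poisson(rs.rate_hz * (duration_s - half - 2.0))
    starts = np.sort(rng.uniform(half + 1.0, duration_s - 1.0 - dur_s, size=n_rip))
    windows: list[tuple[float, float]] = []
    for s in starts:
        if windows and s - windows[-1][0] < dur_s + 0.1:
            continue
        i0 = int(round(s * rate_hz))
        ts.data[i0 : i0 + n_samp] += _ripple_burst(n_samp, rate_hz, rs.freq_hz, rs.amplitude)
        windows.append((float(s), float(s + dur_s)))
    speed, _ = gen_speed_trace([(half, 10.0), (duration_s - half, 0.0)],
                               seed=seed + 1)
    return AwakeSession(lfp=ts, speed=speed, ripple_windows_s=windows,
                        theta_freq_hz=theta_freq_hz, run_until_s=half)


def gen_fs_unit_spikes(
    session: AwakeSession,
    theta_phase_deg: float,
    swr_peaked: bool,
    n_theta_cycles_skip: int = 2,
    spikes_per_swr: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Spike train for one synthetic fast-spiking unit.

    ``theta_phase_deg`` is the trough-referenced preferred theta phase
    (trough = 0); spikes during the running half are placed at that
    phase on every ``n_theta_cycles_skip``-th cycle with small jitter.
    During ripples the unit fires ``spikes_per_swr`` spikes, either
    clustered at the event midpoint (``swr_peaked``) or spread uniformly
    over the event.
    """
    rng = np.random.default_rng(seed)
    f = session.theta_freq_hz
    # trough-referenced deg -> cosine phase fraction of a cycle
    frac = ((theta_phase_deg - 180.0) % 360.0) / 360.0
    n_cyc = int(session.run_until_s * f)
    cycles = np.arange(0, n_cyc - 1, n_theta_cycles_skip)
    theta_spikes = (cycles + frac) / f + rng.normal(0, 0.002, size=cycles.size)
    spikes = [theta_spikes[(theta_spikes > 0) & (theta_spikes < session.run_until_s)]]
    for s, e in session.ripple_windows_s:
        mid, dur = (s + e) / 2.0, e - s
        if swr_peaked:
            sp = rng.normal(mid, dur / 12.0, size=spikes_per_swr)
        else:
            sp = rng.uniform(s, e, size=spikes_per_swr)
        spikes.append(np.clip(sp, s, e - 1e-4))
    # sparse background so the ACG is not empty between events
    n_bg = rng.poisson(2.0 * session.lfp.duration_s)
    spikes.append(rng.uniform(0, session.lfp.duration_s, size=n_bg))
    return np.sort(np.concatenate(spikes))


@dataclass
class ApTemplate:
    """Stereotyped action potential: Gaussian spike above threshold."""

    threshold_mv: float = -45.0
    peak_mv: float = 35.0
    half_width_ms: float = 0.8

    @property
    def amplitude_mv(self) -> float:
        return self.peak_mv - self.threshold_mv


def gen_currentclamp_sweeps(
    rin_mohm: float,
    vm_mv: float,
    step_pa_list: list[float],
    ap_template: ApTemplate | None = None,
    rate_hz: float = 20000.0,
    pre_s: float = 0.2,
    step_s: float = 0.5,
    post_s: float = 0.2,
    tau_m_ms: float = 20.0,
    fi_gain_hz_per_pa: float = 0.1,
    noise_sd_mv: float = 0.1,
    seed: int = 0,
) -> list[TimeSeries]:
    """Stepwise current-injection sweeps with a stereotyped AP template.

    Hyper/subthreshold steps deflect by I*Rin with membrane time constant
    ``tau_m_ms``; suprathreshold steps clamp near threshold and emit
    evenly spaced template APs at ``fi_gain*(I - rheobase)`` Hz.
    """
    if ap_template is None:
        ap_template = ApTemplate()
    rng = np.random.default_rng(seed)
    tau = tau_m_ms / 1000.0
    n_pre = int(pre_s * rate_hz)
    n_step = int(step_s * rate_hz)
    n_post = int(post_s * rate_hz)
    t_step = np.arange(n_step) / rate_hz
    rheobase_pa = (ap_template.threshold_mv - vm_mv) * 1000.0 / rin_mohm
    sigma_s = ap_template.half_width_ms / 1000.0 / (2 * np.sqrt(2 * np.log(2)))
    sweeps = []
    for i_pa in step_pa_list:
        v = np.full(n_pre + n_step + n_post, vm_mv)
        dv_ss = i_pa * rin_mohm / 1000.0  # pA * MOhm -> mV... /1000
        fires = i_pa > 0 and i_pa >= rheobase_pa
        plateau = (ap_template.threshold_mv - vm_mv - 2.0) if fires else dv_ss
        v[n_pre : n_pre + n_step] += plateau * (1 - np.exp(-t_step / tau))
        t_post = np.arange(n_post) / rate_hz
        v[n_pre + n_step :] = vm_mv + plateau * np.exp(-t_post / tau)
        if fires:
            n_aps = max(1, int(round(fi_gain_hz_per_pa * (i_pa - rheobase_pa) * step_s)))
            ap_times = pre_s + (np.arange(n_aps) + 0.5) * step_s / n_aps
            tt = np.arange(v.size) / rate_hz
            base = ap_template.threshold_mv - 2.0
            for at in ap_times:
                v += (ap_template.peak_mv - base) * np.exp(-((tt - at) ** 2) / (2 * sigma_s**2))
        v += rng.normal(0.0, noise_sd_mv, size=v.size)
        sweeps.append(TimeSeries(v, rate_hz, units="mV"))
    return sweeps
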