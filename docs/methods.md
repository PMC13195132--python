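# Methods

This note documents the models and procedures the package implements,
the defaults it ships, the numerical choices behind them, and what the
synthetic-data validation does and does not establish.

## Signal conditioning

All analyses start from a common conditioning chain: second-order
Butterworth band-stop notches at the mains fundamental and harmonics
(50, 100, 150, 250 Hz; −3 dB width 2 Hz — narrow enough to spare the
delta–gamma bands, whose width the acquisition hardware does not
constrain), polyphase FIR anti-aliased downsampling to the 2 kHz
analysis rate, and a 4th-order Butterworth 0.1–300 Hz wideband filter.
Voltage-clamp sweeps are additionally demeaned per sweep to remove slow
drift.

Filters are applied as second-order sections; direct-form high-order
Butterworth filters are numerically unstable with 0.1 Hz corners at
20 kHz. Zero-phase filtering uses forward–backward application with
odd-symmetric edge padding sized at three periods of the slowest corner
frequency; scipy's default padding is far too short for sub-Hz corners
and would leak edge transients into epoch boundaries. Exact
time-reversal symmetry is unattainable for finite signals with any edge
handling; with this padding it holds to about 0.5% and the property test
asserts 1%.

## Spectral parameterization

Spectra are Welch periodograms (Hann window, one-sided density
scaling). LFP analysis uses 10 s windows, 50% overlap and a 0.1 Hz grid
(realized by zero-padding the FFT); synaptic-current spectra use 2 s
windows, 90% overlap, 0.5 Hz steps. Residual mains contamination is
repaired by replacing bins within ±1 Hz of each line frequency with the
mean of the nearest clean flanking bins.

The aperiodic model is the fixed (knee-free) form
`log10 P(f) = offset − χ log10 f`, fitted over 1–100 Hz:

1. an initial least-squares fit, refitted on the lower envelope (the
   2.5% of points with the smallest positive deviation) so narrowband
   peaks do not tilt it;
2. iterative peak extraction on the flattened log spectrum — the tallest
   point above 2 SD of the flattened residual seeds a Gaussian whose
   width comes from the half-height extent, up to 6 peaks, widths
   bounded to 0.5–12 Hz FWHM — followed by a joint bounded
   refinement of all peaks (each width constrained to within a factor
   two of its seed, which stops spurious noise peaks from inflating to
   the bound);
3. a final plain least-squares aperiodic fit with the detected peak
   regions masked out. Masking is used rather than subtracting the
   fitted Gaussians because subtraction propagates peak-fit error into
   the aperiodic parameters; with masking, recovery on synthetic 1/f
   spectra is better than ±0.02 in both offset and exponent across
   χ ∈ [0.5, 2].

The periodic ("peak-only") spectrum is the linear residual
`max(P − 10^model, 0)`, floored at zero so band powers are
non-negative. The slow band (0.1–1 Hz) lies below the fit range; the
aperiodic model is extrapolated down to the lowest positive grid
frequency for the residual there. Band powers are trapezoidal areas
with edge interpolation; normalized powers divide by the 0.1–100 Hz
(LFP) or 0.1–300 Hz (synaptic currents — integrated on the raw
spectrum, since no aperiodic subtraction is defined for currents) total.

## Synaptic-event detection

Detection operates on the sweep at its native rate. The derivative is
the slope of a 0.5 ms boxcar-smoothed trace over a matched 0.5 ms span:
a one-sample derivative at 20 kHz is dominated by noise (an 18 pA event
rising over 1 ms changes ~1 pA per sample against several pA of
sample-to-sample noise), so a smoothing scale below the rise time but
above the sampling interval is required; 0.5 ms is the default and is
configurable (`deriv_smooth_ms`).

Candidates are derivative peaks above mean + k·SD of the derivative
trace (k = 1.8 EPSC / 1.2 IPSC). Each candidate's onset and peak come
from walking the (wider-span) slope back and forward from the
derivative peak; amplitude is the smoothed-trace difference between
them. Candidates then pass four criteria in order: amplitude ≥ 7 pA
(EPSC) / 15 pA (IPSC); start value within 1.5 / 0.3 SD of the baseline
(baseline = trace median; SD = the trace's own standard deviation);
end value within 10 / 70 pA of the start value, which rejects summating
complexes; and a minimum separation of 200 / 100 samples, keeping the
larger event on conflict. The end value is read 30 ms after the peak or
just before the next *distinct* rise, whichever is earlier — candidates
closer than the minimum separation are by definition the same detected
event, so a summating complex is accepted or rejected as a whole rather
than mutually annihilating. All thresholds are per-run configurable and
recorded in the output manifest, since the source protocol treats them
as operator-tuned minima.

Kinetics: amplitude from the event extremum; rise rate as the 20→80%
slope (the maximum dv/dt is also available); decay τ by a bounded
single-exponential fit to the 80→20% post-peak segment, with events
whose segment is too short or breaks the fit flagged and excluded from
means. Charge transfer is the trapezoidal integral of the absolute
baseline-subtracted current, in nA·s; E/I is the ratio of excitatory to
inhibitory charge in the same cell.

The derivative-percentile onset detector (for phase analysis) smooths
with a 2.5 ms boxcar — read as a plain moving average of that width —
takes derivative extrema of the event-appropriate sign, discards
extrema below 1.8 SD of the derivative trace (without this floor,
smoothed-noise extrema at ~200/s swamp the percentile pool and the top
percentiles no longer select events), and keeps the top p% by
magnitude, p ∈ {1, 5, 10, 15, 20, 25}.

## Oscillation epochs

Episodes are detected in the BOSC family with an aperiodic-model
background: Morlet wavelet power (6-cycle wavelets, unit-norm, log-grid
at 3 voices/octave over 1–100 Hz) is thresholded per frequency at the
95th percentile of χ²(2) scaled to the background's mean power — the
wavelet power of a Gaussian process is exponentially distributed — with
the background taken from an aperiodic fit of the *time-averaged wavelet
spectrum itself*, so model and data share units. A run must exceed
`min_cycles/f + 2σ_t(f)` where `σ_t = cycles/(2πf)` is the wavelet's
temporal support: a supra-threshold run overstates the oscillation's
duration by the wavelet's own width, and without the correction a
1.5-cycle transient is smeared past the 2-cycle criterion at adjacent
grid frequencies. Per-frequency episodes are merged per band by the
union of their time supports. On synthetic data this calibrates to
≥99% coverage of a continuous high-SNR 8 Hz oscillation, ~1% false
coverage on pure 1/f noise, and no detections of 1.5-cycle bursts.

## Phase locking

Phase is the analytic-signal angle of the band-passed LFP (0 at the
cosine peak, ±π at the trough). Onsets outside every detected epoch are
discarded (half-open interval convention). Per cell and per percentile
subset: circular mean, vector length `R`, and the finite-n-corrected
Rayleigh p-value from `Z = nR²`; the cell-level R averages across the
six subsets, and subsets with fewer than 10 retained events are
reported missing. Cohort-level locked proportions count cells with
p < 0.05 per subset.

## Units, bursts, firing rates

Spike width is trough-to-subsequent-peak time on the mean waveform
(units without a post-trough peak are excluded). The autocorrelogram
uses ordered spike pairs at lags in (0, 50] ms, 1 ms bins; the first
moment is the count-weighted mean of bin centers, and units whose ACG
peak bin holds fewer than 10 counts are excluded. Classification uses
the strict double inequalities given above; boundary values are
unclassified. Rate categories use half-open `[low, high)` intervals:
pyramidal <1 / 1–5 / >5 Hz, interneuron <25 / 25–40 / >40 Hz. Bursts
are maximal runs — a 4-spike run is one burst of four — at the 5 ms
ISI threshold, with 10 and 15 ms supported for sensitivity analyses;
the ISI distribution reports the cumulative fraction below 5 ms, and a
two-sample KS test (scipy) is surfaced for comparing ISI distributions.

## Sharp-wave ripples and PV⁺ basket cells

The pyramidal-layer channel per shank is the one with the largest mean
150–250 Hz Hilbert-envelope power (ties go to the lowest index). SWR
detection squares the 100–250 Hz envelope, smooths with a Gaussian
(σ = 4 ms, truncated at ±4σ), thresholds at mean + 3 SD of the full
smoothed trace (an exclude-events iterative variant exists behind a
config flag), extends bounds to the nearest mean crossings, and keeps
events that are 15–150 ms long with within-event ripple-band power at
least 4× the identically processed 250–400 Hz control band. The 15 ms
minimum is enforced on the supra-threshold core as well as on the
extended bounds; without that, millisecond noise crossings stretched by
the mean-crossing extension pass the minimum and cost about 20%
precision at envelope SNR 4. Reported per event: duration, cycle count
(peaks of the ripple-filtered trace within bounds), and peak power
z-scored against the full trace.

Peri-SWR modulation divides each event into 8 equal bins centered on
the peak (midpoint) and sums counts over events; the baseline rate
comes from randomly sampled non-theta, non-SWR control windows matched
1:1 in count and duration (seeded sampling). "Single-peaked" is
operationalized as a unique local maximum falling in the two central
bins, with equal-count plateaus merged and maxima below 25% of the
histogram peak ignored as noise — the source protocol names the pattern
but gives no formal test, so this is a declared decision; a bare
strict-inequality local-maximum test fails on exact central ties that
arise for strongly locked units. Theta preference uses an FIR band-pass
(4–12 Hz), Hilbert phase shifted so the trough maps to 0°/360°, 18°
bins, and requires ≥10 in-segment spikes. A putative PV⁺ basket cell is
single-peaked with preference in [203°, 339°].

Behavioral-state segmentation: theta requires multitaper (NW = 3,
5 tapers, 1.6 s windows, 0.8 s steps) theta/delta ratio > 2 — delta is
2–4 Hz in this context, unlike the 1–4 Hz band used elsewhere; both are
kept as the protocol states them — and speed > 5 cm/s (sample-and-hold
aligned); non-theta requires T/D < 2 and speed < 1 cm/s; running/rest
use the speed thresholds alone. Segments shorter than 2 s are
relabelled ambiguous, so the labels always partition the timeline.

## Synthetic data

The generator is the validation substrate and defines the test
conditions:

* **LFP** — the aperiodic background is synthesized by exact spectral
  shaping (rFFT magnitudes set to the target one-sided PSD
  `10^offset/f^χ`, random phases), so the target slope is exact up to
  estimator variance. Oscillations are amplitude-stable cosines with
  optional Lorentzian broadening via Wiener phase diffusion; at zero
  bandwidth the component is exactly `A·cos(2πft)`, matching the
  Hilbert phase convention of the analysis. Ripples are Hann-windowed
  180 Hz bursts (60 ms); the amplitude for a requested envelope SNR —
  peak ripple envelope over the RMS background envelope in 100–250 Hz —
  is computed analytically from the aperiodic PSD.
* **Voltage-clamp sweeps** — biexponential kernels (unit peak, rise
  1 ms, decay 8 ms) at Poisson times, or phase-locked times drawn von
  Mises on a carrier (pure-cosine carriers invert analytically; supplied
  carriers through their monotonized unwrapped Hilbert phase). Defaults
  — 5 Hz events, 20 pA mean amplitude, 2 pA Gaussian noise — follow the
  reported scale of spontaneous excitatory currents in vivo.
* **Spike trains** — refractory-thinned (in)homogeneous Poisson
  background with optional theta-rate modulation
  `r(t) ∝ 1 + d·cos(2πft − φ)`, plus parameterized bursts (n ≥ 3 at a
  fixed intra-burst ISI) injected with guard zones so burst windows are
  unambiguous ground truth.
* **Awake sessions** — a running half with strong pure-cosine theta and
  a resting half with injected ripples, plus the matching 50 Hz speed
  trace; fast-spiking units with designed theta phase preference and
  peri-ripple firing shape support the basket-cell cohort analysis.
* **Current clamp** — RC step responses (τ_m 20 ms) with Gaussian-shaped
  action potentials of specified threshold, peak and half-width.

What the generator does **not** emulate: non-stationarity and movement
artifacts, electrode drift, spike-sorting errors and waveform overlap,
volume conduction across channels (probe channels are statistically
independent), non-Poisson event interactions, and the sharp-wave
(stratum radiatum) component that accompanies real ripples. Passing the
synthetic validation therefore establishes that the implementation
measures what it claims under its stated model, not that the defaults
are optimal for any particular rig's recordings.

## Validation problem sizes

The shipped validation uses 60 s LFP segments at 2 kHz (25 seeds per
exponent for aperiodic recovery), eight 30 s sweeps for the PSC
operating point with 100 noisy replicates for τ recovery, five 60 s
traces with ~20 ripples each at envelope SNR 4, 100 paired 30 s sweeps
for the locked-versus-unlocked discrimination, 100 noise traces for
epoch false-coverage, and one 259-unit fast-spiking cohort on a 120 s
session. These sizes give stable statistics for the stated tolerances;
all randomness is seed-derived.

## Known limitations

* The aperiodic fit assumes a knee-free 1/f over 1–100 Hz; spectra with
  a knee will bias the exponent.
* Detector thresholds are global per sweep/trace; recordings whose
  noise level drifts within a sweep would need per-segment
  re-estimation.
* SWR threshold statistics include the events themselves (the plain
  reading); on event-dense recordings the threshold is correspondingly
  raised. The state-restricted variant is available in config.
* Events closer than the minimum separation are irreducibly reported as
  one event; at 5 Hz Poisson rates this caps recall near 0.95 by
  design.
* The trough-referenced phase convention assumes the pyramidal-layer
  polarity; recordings referenced differently need a sign flip before
  phase analysis.
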