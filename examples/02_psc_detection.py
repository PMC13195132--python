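"""Spontaneous EPSC detection on a synthetic voltage-clamp sweep.

Generates a 30 s sweep with 5 Hz inward events (20 pA mean) on 2 pA
noise, runs the derivative-threshold detector with the default EPSC
configuration, and scores it against the generator's ground truth.
"""
import numpy as np

from hippoephys import patch, synthio
from hippoephys.scoring import match_events

sweep, truth = synthio.gen_psc_sweep(synthio.PscSweepSpec(seed=1))
events = patch.detect_psc(sweep, patch.EPSC_CONFIG, "inward")
freq, amp, iei = patch.event_stats(events, sweep.duration_s)
recall, precision, _ = match_events(
    truth.event_times_s, [e.onset_s for e in events], tol_s=0.010)

print(f"ground-truth events: {truth.event_times_s.size}")
print(f"detected events:     {len(events)}")
print(f"frequency: {freq:.2f} Hz   mean amplitude: {amp:.1f} pA   "
      f"mean IEI: {iei*1000:.0f} ms")
taus = [e.decay_tau_ms for e in events if not np.isnan(e.decay_tau_ms)]
print(f"mean decay tau: {np.mean(taus):.1f} ms  (kernel: 8 ms)")
print(f"recall {recall:.2f} / precision {precision:.2f} at 10 ms tolerance")
print("\nEvents missed are summating pairs the method excludes by design;")
print("precision 1.0 means no noise fluctuation passed the amplitude,")
print("baseline-start and end-match criteria.")
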