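"""Theta phase locking of synaptic-event onsets.

Compares a sweep whose events are locked to an 8 Hz carrier (von Mises,
kappa=4, preferred phase ~29 deg) against a rate-matched unlocked sweep.
Onsets come from the derivative-extremum detector; phases are assigned
only inside detected theta epochs.
"""
import numpy as np

from hippoephys import epochs, patch, phaselock, sigprep, synthio
from hippoephys.core import TimeSeries

rate = 2000.0
t = np.arange(int(30.0 * rate)) / rate
rng = np.random.default_rng(0)
lfp = TimeSeries(np.cos(2 * np.pi * 8.0 * t) + rng.normal(0, 0.1, t.size), rate)
theta = sigprep.bandpass(lfp, 4.0, 12.0)
eps = epochs.detect_osc_epochs(lfp, "theta")
print(f"theta epochs cover {sum(e.duration_s for e in eps):.1f} of 30 s")

for kappa, label in [(4.0, "locked (kappa=4)"), (0.0, "unlocked")]:
    sweep, _ = synthio.gen_psc_sweep(synthio.PscSweepSpec(
        duration_s=30.0, rate_hz=rate, event_rate_hz=5.0,
        locking=(8.0, kappa, 0.5), seed=2))
    onsets, strengths = patch.derivative_onsets(
        sweep, "inward", 100.0, return_strengths=True)
    res = phaselock.phase_lock_analysis(onsets, theta, eps, "theta",
                                        onset_strengths=strengths)
    d = res.per_threshold[25]
    print(f"{label:>18}: mean R = {res.mean_vector_length():.3f}, "
          f"circ mean = {np.degrees(d['circ_mean_rad']):6.1f} deg, "
          f"Rayleigh p (top 25%) = {d['rayleigh_p']:.2g}")
print("\nR near 0.86 matches the von Mises expectation I1(4)/I0(4); the")
print("unlocked sweep shows no significant phase preference.")
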