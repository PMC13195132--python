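# Preset: anesthetized voltage-clamp (PSC) analysis.
# PSC spectra: Welch 2 s window / 90% overlap / 0.5 Hz step, normalized
# by total power 0.1-300 Hz; phase locking uses the 1-25% derivative
# percentile subsets inside fBOSC-detected delta/theta epochs.
welch:
  psc: {window_s: 2.0, overlap_frac: 0.9, step_hz: 0.5}
norm_range_hz:
  psc: [0.1, 300.0]
onsets:
  percentiles: [1, 5, 10, 15, 20, 25]
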