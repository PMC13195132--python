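# Preset: anesthetized single-channel LFP analysis.
# Welch 10 s window / 50% overlap / 0.1 Hz step; aperiodic fit over
# 1-100 Hz; normalization range 0.1-100 Hz (the lfp norm key).
welch:
  lfp: {window_s: 10.0, overlap_frac: 0.5, step_hz: 0.1}
norm_range_hz:
  lfp: [0.1, 100.0]
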