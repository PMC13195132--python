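# Preset: awake silicon-probe analysis.
# Pyramidal-layer channel by 150-250 Hz envelope power; T/D state
# segmentation uses the 2-4 Hz delta variant; SWR detection 100-250 Hz
# vs 250-400 Hz control band.
epochs:
  td_theta_hz: [4.0, 12.0]
  td_delta_hz: [2.0, 4.0]
swr:
  ripple_band_hz: [100.0, 250.0]
  control_band_hz: [250.0, 400.0]
  threshold_sd: 3.0
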