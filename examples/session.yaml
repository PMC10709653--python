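# End-to-end pipeline config for `olcam run`.
# Omitted keys take the rule-set defaults (5 z, 4 frames, 1 z, 10%,
# 7 z, 1 Hz, 0.2 s, mean+1SD, 20%, 2.5 s, 30 s, A/R 1.5).
seed: 5

sim:
  duration_s: 120
  n_bouts: 1
  bout_dur_s: 30
  n_microdomains: 8
  field_um: 14

detection:
  amp_thresh_z: 5.0
  min_dur_frames: 4

behavior:
  extension_s: 2.5
  rest_min_s: 30.0
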