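# Example pipeline configuration for `spindlecnn --config ...`.
# Every key is optional; omitted keys fall back to the documented defaults.

generator:
  fs_hz: 1024.0
  record_duration_s: 600.0
  channel_names: [C3, C4]
  spindle_rate_per_min: 3.0
  noise_exponent: 1.0        # spectral slope beta of the 1/f^beta background
  noise_scale_uv: 40.0       # broadband background RMS in microvolts
  min_gap_s: 2.0

preprocess:
  target_fs_hz: 100.0
  band_hz: [0.3, 30.0]
  fir_window: hamming
  zscore_scope: per_channel_recording   # or per_window

windowing:
  window_s: 3.0
  guard_s: 0.5

train:
  epochs: 100
  batch_size: 128
  lr0: 0.1                   # 0.001 is the robust alternative on hard data
  lr_decay_factor: 0.75
  lr_decay_every_epochs: 3
  weight_decay: 0.01
  fold_grouping: by_subject  # or by_window
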