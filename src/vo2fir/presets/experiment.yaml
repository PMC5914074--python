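# Breath-by-breath onset pipeline at the experimental settings: FIR order 300,
# stable-spline kernel (c=1, lambda=0.978), gamma=4, alpha=10, plus the
# default 20-subject synthetic cohort to exercise it.
pipeline:
  m: 300
  kernel: {kind: ss, c: 1.0, lambda: 0.978}
  gamma: 4.0
  alpha: 10.0
  arx_max_order: 20
cohort:
  n_subjects: 20
  seed: 0
  snr_db: 3.0
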