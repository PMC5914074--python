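# Monte-Carlo benchmark on first-order plants: gain ~ U(10,20), Tp ~ U(10,20),
# unit step at 180 s for 300 s, 3 dB output noise, FIR order 120.
study:
  reps: 1000
  plant_order: 1
  snr_db: 3.0
  m: 120
  gamma: 8.0
  alpha: 10.0
  seed: 0
  kernels:
    ss: {kind: ss, c: 1.0, lambda: 0.98}
    dc: {kind: dc, c: 1.0, lambda: 0.9, rho: 0.8}
    di: {kind: di, c: 1.0, lambda: 0.9}
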