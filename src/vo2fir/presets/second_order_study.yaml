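# Monte-Carlo benchmark on second-order plants: gain ~ U(10,20),
# tau1 ~ U(10,20), tau2 ~ U(5,10); ARX baselines at orders (1,1) and (2,2).
study:
  reps: 1000
  plant_order: 2
  snr_db: 3.0
  m: 120
  gamma: 8.0
  alpha: 10.0
  seed: 0
  arx_orders: [[1, 1], [2, 2]]
  kernels:
    ss: {kind: ss, c: 1.0, lambda: 0.98}
    dc: {kind: dc, c: 1.0, lambda: 0.9, rho: 0.8}
    di: {kind: di, c: 1.0, lambda: 0.9}
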