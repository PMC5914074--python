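# vo2fir

Nonparametric modelling of oxygen-uptake (VO2) on-kinetics during treadmill
exercise, by **kernel-regularized, L1-sparsified FIR identification** from a
single walk-to-run speed step.

## The problem

Breath-by-breath VO2 measured by a portable gas analyser is irregularly
sampled and extremely noisy, and the only practical excitation during a
treadmill session is a single speed step (e.g. walking at 3 km/h, then
running at 8 km/h). Under those conditions classical parametric
identification struggles: the model order is unknowable from a step response,
and plain least squares on a finite-impulse-response (FIR) model amplifies
the noise. `vo2fir` estimates the impulse response g = [g_1, ..., g_m] of the
speed-to-VO2 system

    y(t) = Σ_{i=1..m} g_i u(t-i) + ε(t)

by minimizing the **kernelized elastic net**

    ||Y - Φθ||² + γ θᵀP⁻¹θ + α ||θ||₁ ,

where P is a prior covariance (kernel) encoding exponential decay of the
impulse response — stable-spline (SS), diagonal/correlated (DC) or diagonal
(DI) — γ weights that smoothness prior and α sparsifies the tail of the
estimate. The problem is reduced to a plain lasso through the augmentation
Φ* = (1+γ)^(-1/2) [Φ; √γ R], Y* = [Y; 0] with RᵀR = P⁻¹ (upper Cholesky
factor), solved exactly by the LARS homotopy with a duality-gap certificate,
and mapped back via θ = θ*/√(1+γ).

The package also provides the classical baseline (ARX fitted by least
squares — the prediction-error method for that structure — with AIC order
selection), a Monte-Carlo benchmark on random first/second-order plants at
3 dB SNR, the full breath-by-breath preprocessing pipeline (median filter,
1-s resampling, onset-window construction), and a synthetic cohort generator
with known ground truth so the entire experimental procedure is testable
without any recorded data.

Audience: researchers in exercise physiology / cardiorespiratory modelling
and anyone identifying slow LTI dynamics from poor step excitation under
heavy noise.

## Worked example

Estimate a subject's impulse response from a (synthetic) breath-by-breath
session:

```python
from vo2fir import CohortSpec, generate_cohort
from vo2fir.pipeline import process_record

cohort = generate_cohort(CohortSpec(n_subjects=1, seed=7))
rec, truth = cohort[0]            # BreathRecord + ground-truth parameters
ds, res = process_record(rec)     # preprocess + estimate (m=300, SS kernel)
print(res.results.summary())
```

prints

```
Kernelized elastic-net FIR estimation
==============================================
samples (M)          : 900
FIR order (m)        : 300
regression rows (N)  : 600
kernel               : SS (c=1, lam=0.978)
gamma / alpha        : 4 / 10
solver status        : converged (2116 iterations, duality gap 4.647e+01)
objective value      : 1.59409e+08
zero coefficients    : 0 / 300
step-response gain   : 2184
fit ratio (measured) : 0.4839
```

The step-response gain (sum of the 300 impulse-response coefficients) is the
steady-state VO2 increase for the walk-to-run transition: 2184 ml/min here
against a generator truth of 2091 ml/min, recovered through ~3 dB of
measurement noise. The fit ratio is the NRMSE goodness of fit
1 − ‖ŷ−y‖/‖y−mean(y)‖ against the *measured* (noisy) output over samples
301–900; at 3 dB SNR values near 0.5 are the achievable ceiling. The duality
gap certifies the solver: 46.5 on an objective of 1.6e8 is 3e-7 relative.

A statsmodels-style front-end is available for arbitrary input/output
records:

```python
from vo2fir import KernelFIR, ARX
res = KernelFIR(endog=y, exog=u, m=120, gamma=8.0, alpha=10.0).fit()
res.summary(); res.impulse_response; res.fit_ratio()
base = ARX(endog=y, exog=u, na=2, nb=2).fit()
```

## Command line

```bash
vo2fir simulate-study config.yaml --out results/   # Monte-Carlo benchmark
vo2fir make-cohort config.yaml --out cohort/       # synthetic breath data
vo2fir vo2-fit cohort/subject_*.csv --out fits/    # per-subject estimation
```

Preset configurations live in `src/vo2fir/presets/`
(`first_order_study.yaml`, `second_order_study.yaml`, `experiment.yaml`).
Every output directory contains a `manifest.json` (config hash + seed +
version) sufficient to reproduce it byte-for-byte.

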