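# tvmvar

Time-varying MVAR coefficient estimation under unknown noise, for
directed (effective) connectivity analysis of multichannel neural
recordings — EEG, MEG (including OPM-MEG) sensor or source time
series, or any multichannel signal modeled as a multivariate
autoregression.

Granger-causal connectivity rests on the MVAR model

    X_t = Σ_{r=1..p} A_{r,t} X_{t−r} + E_t ,

whose coefficients A_{r,t} must be tracked over time for non-stationary
neural signals. The usual sequential estimator, a Kalman filter on the
state-space form a_t = a_{t−1} + w_t, x_{i,t} = H_t a_t + v_t, is
optimal only for Gaussian noise — while real recordings carry
heavy-tailed and 1/f noise of unknown statistics. The core of this
package is a **cost-reference particle filter (CRPF)**: a sequential
Monte Carlo estimator that replaces likelihoods with a user-defined
accumulated cost

    C_t^i = λ C_{t−1}^i + |x_t − H_t a_t^i|^q ,

resamples particles on the matching risk through a monotone decreasing
weight map (R^i − min R + δ)^(−β), propagates them with an annealed
Gaussian jitter, and estimates â_t as the cost-weighted particle mean —
no noise densities anywhere. Kalman (KF) and maximum-correntropy (MCF)
filters are included as baselines under one shared contract, plus:

- a simulator for time-varying MVAR benchmarks and three noise
  families (Gaussian, alpha-stable via the Chambers–Mallows–Stuck
  transformation, pink via spectral shaping);
- squared partial directed coherence, sPDC_ij(f) = |Ā_ij(f)|² /
  Σ_m |Ā_mj(f)|² with Ā(f) = I − Σ_r A_r e^(−i2πfr/fs), and in/outflow
  summaries;
- bootstrap condition contrasts on sPDC grids with per-pair
  Benjamini–Hochberg FDR;
- FPE model-order selection and a benchmark harness that reproduces
  the simulation study the estimators were validated on.

Estimators follow scikit-learn conventions (`fit(X)` on an
`(n_samples, n_channels)` array, fitted `coeffs_` / `diverged_`
attributes, `get_params`/`set_params`), so they compose with sklearn
tooling; functional wrappers (`kf_estimate`, `mcf_estimate`,
`crpf_estimate`) operate on the channels-by-samples `TimeSeries`
container.

## Worked example

Track a 3-channel benchmark system with three time-varying couplings
(a step, a 0.05 Hz oscillation, a ramp) driven by shifted-Cauchy noise
— the regime where the Kalman filter breaks down:

```python
import numpy as np
import tvmvar

# simulate 10 s of the 3-channel benchmark under Cauchy-like noise
traj = tvmvar.benchmark_trajectory(n_samples=10_000, fs=1000.0)
ts = tvmvar.simulate_mvar(traj, tvmvar.NoiseSource(
    kind="alpha_stable",
    stable=tvmvar.AlphaStableParams(alpha=1.0, beta=0.0, gamma=1.0, a=0.75)),
    fs=1000.0, seed=0)

# fit the cost-reference particle filter and the Kalman baseline
crpf = tvmvar.CostReferenceMVAR(order=2, n_particles=1000, random_state=0).fit(ts.data.T)
kf = tvmvar.KalmanMVAR(order=2).fit(ts.data.T)

err_crpf = tvmvar.coefficient_error(traj, crpf.to_trajectory())
err_kf = tvmvar.coefficient_error(traj, kf.to_trajectory())
print(f"tracking error (time-varying couplings): CRPF {err_crpf:.4f}, KF {err_kf:.4f}")

# directed connectivity from the estimated coefficients
grid = tvmvar.spdc(crpf.to_trajectory(), fs=1000.0,
                   freqs=np.arange(5.0, 205.0, 10.0),
                   times=np.arange(2, 10_000, 100))
flow = tvmvar.flow_summary(grid, direction="out", zscore=True)
late = flow.times >= 6000
print("mean z-scored outflow after the coupling step, per channel:",
      np.round(flow.values[:, late].mean(axis=1), 2))
```

Output:

```
tracking error (time-varying couplings): CRPF 0.0271, KF 0.3992
mean z-scored outflow after the coupling step, per channel: [ 1.07 -0.38  1.02]
```

The CRPF tracks the three couplings with a mean absolute error of
0.027 under heavy-tailed noise where the Kalman filter's error is 15×
larger. The flow summary shows what the estimated network implies:
channel 1's outflow rises after mid-run (its coupling onto channel 3
steps on at 5 s) and channel 3's rises with the ramping coupling onto
channel 1, while channel 2 — which receives nothing — shows no
increase.

The same pipeline is scriptable from the shell:

```sh
tvmvar simulate --noise alpha_stable --duration 10 --seed 0 --output sim.tsv
tvmvar estimate --method crpf --order 2 --input sim.tsv --output est.npz
tvmvar spdc --trajectory est.npz --fs 1000 --output grid.npz
tvmvar flow --grid grid.npz --direction out --zscore --output flow.tsv
tvmvar benchmark --trials 10 --duration 20 --report table.csv
```

## Benchmark reproduction

`scripts/acceptance.py` recomputes the simulation-study error table
from scratch: it simulates the benchmark system (10 trials × 20 s at
1 kHz) under each of the three noise regimes, runs all three
estimators at their standard settings (KF/MCF with Q=10, R=1e4, kernel
width 50; CRPF with 1000 particles), scores every trial by the mean
absolute tracking error of the time-varying couplings, and writes the
per-cell means to JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run takes roughly 10 minutes on one CPU. `docs/methods.md`
documents the model, every default, and the known limitations of the
reproduction.
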