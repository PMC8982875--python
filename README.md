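# oscdecomp

Oscillator decomposition of bivariate hemodynamic (fNIRS) time series with
Gaussian linear state-space models.

fNIRS channels record paired oxy- and deoxy-hemoglobin concentration
changes that mix slow cerebral hemodynamics with cardiac pulsation and
instrument noise. Instead of choosing bandpass filters by hand, this
package models a channel as a superposition of K latent stochastic
oscillators

    x_{t+1}^{(k)} = a_k R(2π f_k Δt) x_t^{(k)} + v_t^{(k)},   v ~ N(0, σ²_k I₂)
    y_{t,j} = Σ_k c_{jk}·x_t^{(k)} + w_{t,j},                 w ~ N(0, τ²)

where R(θ) is a rotation, a_k ∈ (0,1) is the oscillator's regularity, f_k
its frequency and σ²_k/(1−a²_k) its power; the projection c_{jk} carries
the amplitude and the phase delay arg(c_{jk,1} + i c_{jk,2}) of oscillator
k on series j (series 1 is the reference, c_{1k} ≡ (1,0)). Parameters are
estimated by maximum marginal likelihood via the Kalman filter, the number
of oscillators by AIC, and oscillator trajectories by the Kalman smoother.

On top of the decomposition the package provides:

* classification of fitted oscillators into brain (0.01–0.1 Hz,
  oxy→deoxy delay ≈ 230°), cardiac pulse wave (~2 Hz, in phase),
  mirroring noise (~2 Hz, anti-phase — the Lambert–Beer image of
  per-wavelength measurement noise) and pulse harmonic (~4 Hz);
* a test of the common-oscillator hypothesis: joint bivariate model versus
  two independent univariate models, compared by AIC with a Linhart-type
  z test and a Wilcoxon signed-rank check on the per-time predictive
  densities;
* frequency-specific functional connectivity: canonical correlations
  between the smoothed oscillator trajectories of channel pairs,
  thresholded networks, and channel-pair group summaries (short-range /
  contralateral-transverse / ipsilateral-longitudinal / control);
* the conventional baseline (zero-phase bandpass + Hilbert phase + von
  Mises circular statistics) and delta-method confidence intervals for
  phase differences from the observed Fisher information;
* synthetic generators reproducing this statistical structure, including a
  fully specified 3-oscillator benchmark and multi-channel scenarios with
  controlled cross-channel coupling.

See `docs/methods.md` for the model, estimation details, and design
choices.

## Worked example

Decompose one realization of the benchmark generator — a slow oscillator
at 0.03 Hz whose deoxy projection is delayed by 230°, plus a sharp
anti-phase and a broad in-phase oscillator at 2 Hz:

```python
import numpy as np
from oscdecomp import (FitConfig, fit_oscillators, phase_difference_ci,
                       classify_oscillators, three_oscillator_series)

data, truth = three_oscillator_series(seed=42)   # N=1800, 10 Hz, (oxy, deoxy)
decomp = fit_oscillators(data, kmax=5, config=FitConfig(n_starts=1))
print("selected K:", decomp.best_K)
for lab in classify_oscillators(decomp):
    print(f"  f={lab.frequency:6.3f} Hz  a={lab.regularity:.3f}  power={lab.power:.4f}  "
          f"phase={lab.phase_diff_deg:6.1f} deg  deoxy norm={lab.deoxy_norm:.2f}  -> {lab.kind}")
ci = phase_difference_ci(decomp.best, data, j=1, k=0)
print(f"slow-oscillator hPod: {ci.estimate_deg:.2f} deg, 95% CI "
      f"[{ci.ci95[0]:.2f}, {ci.ci95[1]:.2f}]")
mse = np.mean((decomp.components[0, 0] - truth.component(0, 0))**2)
print(f"slow-component reconstruction MSE: {mse:.2e}")
```

Output:

```
selected K: 3
  f= 0.026 Hz  a=0.988  power=0.0079  phase= 229.0 deg  deoxy norm=0.52  -> brain
  f= 1.999 Hz  a=0.993  power=0.0154  phase= 182.0 deg  deoxy norm=0.96  -> mirror
  f= 2.045 Hz  a=0.395  power=0.0098  phase=   2.4 deg  deoxy norm=0.20  -> pulse
slow-oscillator hPod: 229.03 deg, 95% CI [219.52, 238.53]
slow-component reconstruction MSE: 4.58e-04
```

All three oscillators are recovered with their projection patterns: the
slow component's phase delay is estimated at 229° (truth 230°) with a CI
that covers the truth, and its reconstruction error (4.6e-4 against a
signal of variance 0.01) is about an order of magnitude below what
bandpass filtering achieves on the same data. Note the two cardiac-band
oscillators overlap completely in frequency and are separated only through
their projection patterns — a filter cannot do this.

There is also a command-line pipeline:

```sh
oscdecomp simulate --scenario fnirs --seed 1 --out data.csv
oscdecomp decompose --data data.csv --kmax 5 --out results/
oscdecomp connectivity --data data.csv --band 0.01:0.1 --threshold 0.6 --out net/
```

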