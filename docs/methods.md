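# Methods

## Model

`oscdecomp` decomposes a J-dimensional time series y = (y_{t,j}), t = 1..N,
sampled at period Δt, into K latent stochastic oscillators. Oscillator k is
a point (x₁, x₂) in the plane obeying a damped stochastic rotation

    x_{t+1}^{(k)} = a_k R(2π f_k Δt) x_t^{(k)} + v_t^{(k)},
    v_t^{(k)} ~ N(0, σ²_k I₂),

with regularity a_k ∈ (0, 1) (closer to one = more sinusoidal, narrower
spectral peak), frequency f_k in Hz (0 ≤ 2π f_k Δt ≤ π), and innovation
variance σ²_k. The stationary variance of each coordinate — the
oscillator's power — is σ²_k / (1 − a²_k). Observations superpose the
oscillators through projection vectors c_{jk} = (c_{jk,1}, c_{jk,2}):

    y_{t,j} = Σ_k ( c_{jk,1} x_{t,1}^{(k)} + c_{jk,2} x_{t,2}^{(k)} ) + w_{t,j},
    w_{t,j} ~ N(0, τ²),

so oscillator k appears on series j scaled by ‖c_{jk}‖ and phase-delayed by
arg(c_{jk,1} + i c_{jk,2}). For identifiability c_{1k} ≡ (1, 0): series 1
(oxy-Hb for fNIRS) is the amplitude and phase reference. The pair is a
Gaussian linear state-space model; the Kalman filter gives the exact
marginal likelihood by prediction-error decomposition, and the
Rauch–Tung–Striebel smoother gives exact posteriors of every oscillator
coordinate. The filter initializes from the stationary distribution
(mean 0, block covariance σ²_k/(1 − a²_k) I₂), so the first per-time log
predictive density l₁ is defined from the stationary law.

For fNIRS the intended reading is: a slow (0.01–0.1 Hz) "brain" oscillator
whose deoxy projection has norm ≈ 0.5–0.7 and phase delay ≈ 230°; a sharp
~2 Hz cardiac pulse wave, in phase on both chromophores with deoxy norm
≈ 0.2; a low-regularity (a ≈ 0.4) ~2 Hz "mirroring noise" component in
anti-phase with deoxy norm ≈ 1, which is what per-wavelength measurement
noise looks like after the two-wavelength Lambert–Beer inversion; and
optionally the ~4 Hz pulse harmonic.

## Fitting and model selection

Parameters θ_K = (a, f, σ², c, τ²) are estimated by maximizing the marginal
likelihood with L-BFGS-B on transformed coordinates (logit for a, scaled
logit onto (0, Nyquist) for f, log for σ² and τ², free projection entries);
gradients are finite-difference. a is bounded at 1 − 10⁻⁶. Frequencies are
initialized from the complex roots of a Yule–Walker AR(2K) fit to the
reference series (root modulus → a, argument → 2π f Δt); positive real
roots are kept as near-DC candidates because a slow oscillator's tiny
rotation angle collapses to a real root at these AR orders. Innovation
variances partition the reference-series variance; projections start in
phase at the regression amplitude of each series on the reference. Fits can
multi-start (AR start plus deterministic jitters, default 3 starts) and,
optionally (`warm_start`), chain across K: the K+1 fit also starts from the
previous optimum augmented by one oscillator at the dominant residual
periodogram frequency. The best likelihood wins; fitted oscillators are
reported sorted by frequency. Optimizer budget: 500 iterations by default.

K is selected by minimizing AIC(K) = −2 log p(y | θ̂_K) + 2 ((J+2)K + 1),
the method's conventional penalty count (`aic_penalty="effective"`). For
J ≥ 2 that count is smaller than dim(θ_K) = (2J+1)K + 1; the
dimension-consistent count is available as `aic_penalty="full"`. The two
coincide for univariate data.

A caveat we quantified on the benchmark generator (below): with a thorough
optimizer, adding a spurious extra oscillator with a free frequency
effectively scans the residual periodogram, so the attainable spurious gain
in 2·log-likelihood is on the order of the maximum of ~N/2 exponential
ordinates, ≈ 2·log(N/2) ≈ 13.6 at N = 1800 — larger than either penalty
(8 effective, 10 full per oscillator at J = 2). Plain AIC is therefore an
anti-conservative selector for this model class at this length, and the
selected K can exceed the generating K with appreciable probability; the
spurious components are weak (power ≲ 5% of the real ones) and do not
disturb the recovered frequencies, phases, or components. See "Known
limitations".

## Phase differences and confidence intervals

The phase delay of oscillator k on series j is arg(c_{jk,1} + i c_{jk,2}),
reported in degrees [0, 360) (positive = series j lags the reference). Its
95% CI comes from the observed Fisher information: the Hessian of the
negative log marginal likelihood at the MLE in natural coordinates, by
central finite differences with per-parameter scaled steps (relative scale
10⁻⁴, floor 10⁻²), inverted to a covariance; the delta method with gradient
(−c₂, c₁)/(c₁² + c₂²) then gives the phase variance (and (c₁, c₂)/‖c‖ the
norm variance). Smoother intervals on trajectories and components are
posterior credible intervals; parameter intervals are Wald CIs. CI
endpoints are not wrapped into [0, 360).

## Common-oscillator test

For a bivariate channel, the joint J = 2 model (shared oscillators) is
compared with two independent univariate fits (each with its own
AIC-selected K; combined AIC and per-time predictive densities are sums).
The Linhart-type statistic is

    z = (AIC⁽¹⁾ − AIC⁽²⁾) / ( 2 √N · sqrt(Σ₁₁ + Σ₂₂ − 2 Σ₁₂) ),

where Σ is the (population, 1/N) covariance of the paired per-time log
predictive densities; z is approximately standard normal when the models
fit equally well and p = 2(1 − Φ(|z|)). The parenthesization makes z
scale-correct (AIC difference O(N), denominator O(√N · sd)). A Wilcoxon
signed-rank test on the paired l_t (zeros dropped, tie-corrected normal
approximation for long series) provides a normality-free check. Pointwise
identical densities make the variance term degenerate and raise an error.

## Classification and connectivity

Fitted oscillators of a bivariate channel are labeled from frequency and
phase delay alone: brain 0.01–0.1 Hz; within 1.6–2.4 Hz, pulse if the
delay is within 90° of 0°, mirror if within 90° of 180° (the midpoint
split between the two observed phase peaks; configurable); harmonic
3.6–4.4 Hz; otherwise other. Projection norms are reported but are not
classification criteria.

For a frequency band, each channel contributes the smoothed bivariate
trajectory of its maximum-power in-band oscillator (power = latent
stationary variance; ties break toward the lower index; an optional
in-phase/anti-phase restriction separates pulse from mirroring noise in
the shared cardiac band). Channel pairs are scored by the first canonical
correlation — the largest singular value of the whitened cross-covariance,
equal to the maximal Pearson correlation over linear projections —
computed on the smoothed posterior means. Thresholding (0.7/0.6/0.5/0.4)
yields networks; channel pairs are grouped as short-range (same
hemisphere, adjacent), contralateral-transverse (opposite hemispheres,
position difference ≤ 1), ipsilateral-longitudinal (same hemisphere,
difference ≥ 5), or control, which on the L1–L9/R1–R9 layout gives
16/25/20/92 of the 153 pairs. The conventional baseline correlates
bandpassed signals per chromophore (Pearson).

## Bandpass + Hilbert baseline

The comparator pipeline bandpasses with a zero-phase Butterworth filter
(order 4 per edge, applied forward–backward; maximally flat passband,
> 40 dB at 2 Hz for the 0.01–0.1 Hz band), takes per-time phase
differences from analytic-signal angles, and summarizes them by the von
Mises mean direction with the standard resultant-length CI (as in common
circular-statistics toolboxes). Two deficiencies are intentional
properties of the baseline, not bugs: filtfilt startup transients near the
record ends for bands with very low edges, and a CI that treats serially
dependent per-time phases as independent draws and is therefore optimistic
— part of why the baseline's interval typically excludes the true phase
difference.

## Synthetic generators

`three_oscillator_series` is the fully specified benchmark: K = 3,
N = 1800, Δt = 0.1 s, a = (0.99, 0.99, 0.4), f = (0.03, 2, 2) Hz,
σ²_k = 0.01(1 − a²_k) (every oscillator has power 0.01), deoxy projections
0.5∠230°, −1, and 0.2, τ² = 10⁻⁶. `noise_sweep` re-observes one latent
realization under a τ² grid.

`fnirs_like` generates multi-channel (default 18, L1–L9/R1–R9) bivariate
data with the three classes at their observed projection patterns: brain
(f drawn once per subject from U[0.02, 0.03] Hz, a = 0.995, deoxy norm
0.6 at 230°), pulse (2.0 Hz, a = 0.99, norm 0.2 in phase), mirror
(2.07 Hz, a = 0.4, norm 1 in anti-phase, present in a random 80% of
channels), optional 4 Hz harmonic; powers default to 0.01 (0.0025 for the
harmonic) and τ² = 10⁻⁵. Cross-channel synchrony is induced through
correlated innovations, applied coordinate-wise, which keeps every channel
marginally an exact oscillator model: the pulse is globally coupled at
0.95, mirroring noise is independent, and brain innovations follow a
spatial correlation built from the probe geometry (squared-exponential
kernel over two rails plus a global background and nugget; defaults put
same-hemisphere adjacent pairs near 0.7, homologous contralateral pairs
near 0.65, and distant pairs near 0.2). The kernel construction is used
because assigning one exact correlation per pair group is not jointly
positive semidefinite on the 18-channel layout — no generator can realize
those values — whereas the kernel is positive definite for any channel
subset and reproduces the intended group ordering. An explicit group-valued
coupling override remains available and raises a named error when
infeasible. Brain oscillators share one base frequency within a subject
(innovation coupling only sustains synchrony between equal rotation
frequencies); per-channel jitter is available but defaults to zero.

What the generator deliberately does not emulate: raw light-intensity
physics, motion artifacts, probe-coupling dropouts, nonstationarity,
respiration, and amplitude scales calibrated to real recordings. Passing
tests therefore demonstrate correct recovery of the assumed statistical
structure, not robustness to real-world artifacts.

`mirror_from_wavelength_noise` implements the Lambert–Beer mechanism: with
extinction coefficients ε_o(λ), ε_d(λ), pathlength L and optical-density
noise N(λ), the inversion errors are ΔC_o^e − ΔC_o^r = −E(ε_d(λ₂)N(λ₁) −
ε_d(λ₁)N(λ₂)) and ΔC_d^e − ΔC_d^r = +E(ε_o(λ₂)N(λ₁) − ε_o(λ₁)N(λ₂)),
E = 1/((ε_o(λ₂)ε_d(λ₁) − ε_o(λ₁)ε_d(λ₂))L) — opposite-sign loadings on
each wavelength's noise. The default coefficients are nominal 785/830 nm
values; only the sign structure and scale depend on them, and the closed
forms are verified against a direct linear solve. `shuffled_pairs` builds
cross-subject derangements (oxy from one subject, deoxy from another) for
the common-oscillator null comparison.

## Numerical choices

* Compiled likelihood kernel (numba) exploiting the block-rotation
  transition: O((2K)²) predict step, analytic 2×2 innovation inverse,
  symmetrized covariance updates each step (long recursions with a_k near
  one drift otherwise). The reference NumPy filter uses the Joseph-form
  update; both agree with brute-force joint-Gaussian oracles to 1e-8 on
  small problems.
* Spectra: a component's density at frequency f is the transfer form
  c'(e^{iω}I − F_k)⁻¹ Q_k (e^{−iω}I − F_kᵀ)⁻¹ c with ω = 2πfΔt, scaled by
  Δt so the integral over [−Nyquist, Nyquist] equals the component's
  stationary variance; the observation noise adds a flat floor τ²Δt. This
  normalization makes the Welch-periodogram cross-check well-posed.
* CCA: Cholesky whitening with a 1e-10·scale ridge (and a warning) for
  rank-deficient within-set covariances; results clipped to [0, 1].
* Degenerate inputs raise informative errors rather than propagating NaN:
  singular innovation covariances, non-PSD coupling matrices, zero
  projection vectors (undefined phase), near-uniform angle samples
  (undefined mean direction), pointwise-identical model densities.

## Study sizes used by the test suite and acceptance script

The acceptance script fits one benchmark realization (N = 1800, K = 1..5,
single AR start, 500 iterations) and reports the selected K, the slow and
first fast frequencies, the slow oscillator's deoxy phase delay with its
delta-method CI lower endpoint, and the bandpass+Hilbert circular mean.
The test suite runs ten benchmark realizations for the same pipeline; a
two-subject, five-channel, N = 900 study (no mirroring noise, Kmax = 3)
for the common-oscillator comparison including shuffled pairs; fits with
the planted K on an 18-channel N = 1200 scenario for connectivity; and a
two-seed noise sweep at τ² ∈ {10⁻⁶, 10⁻⁴} with K fixed at 3. These sizes
were chosen so the whole suite completes on a single CPU while every
qualitative contrast retains a decisive margin (AIC margins in the
comparison study are several hundred units; connectivity contrasts are
0.2–0.5 in correlation).

## Known limitations

* AIC overfitting at the margin, as quantified above: on the benchmark
  generator the fully optimized fit selects K = 3 in roughly two-thirds of
  realizations and otherwise K = 4–5 with weak extra components. Published
  single-realization selections of the generating K are reproducible only
  when the optimizer fails to find the spurious periodogram-scan optima;
  we report what the likelihood surface actually supports. The
  dimension-consistent penalty (`aic_penalty="full"`) raises the correct
  selection rate only modestly.
* The delta-method phase CI relies on a positive-definite observed
  information; near-degenerate fits (e.g. a at its bound) raise instead of
  returning a fabricated interval.
* Missing data are rejected, not imputed; series must be uniformly
  sampled.
* The baseline's circular CI inherits the independence assumption noted
  above by design.
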