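"""Maximum marginal likelihood fitting of oscillator models and AIC selection.

For each candidate number of oscillators K the marginal likelihood is
maximized by bounded quasi-Newton (L-BFGS-B with finite-difference
gradients) over transformed parameters: logit for the regularities a_k,
scaled logit onto (0, Nyquist) for the frequencies f_k, log for the
variances sigma2_k and tau2, and unconstrained projection entries.  K is
then selected by minimizing AIC(K).

Frequencies are initialized from the complex roots of an autoregressive fit
of order 2K to the reference series (root modulus -> a, root argument ->
2*pi*f*dt), with jittered restarts.  Phase differences between series carry
delta-method confidence intervals based on the observed Fisher information
(finite-difference Hessian of the negative log marginal likelihood at the
MLE).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.optimize import minimize
from scipy.special import expit, logit

from .ssm_core import (
    OscillatorParams,
    OscModel,
    StateTrajectory,
    TimeSeriesData,
    kalman_smoother,
    loglik_per_time,
)
from ._kalman import filter_loglik

__all__ = [
    "FitConfig",
    "FitResult",
    "DecompResult",
    "PhaseDifferenceEstimate",
    "initialize_params",
    "fit_single_k",
    "fit_oscillators",
    "observed_information",
    "phase_difference_ci",
    "oscillator_power",
]

_A_LO = 1e-6


@dataclass
class FitConfig:
    """Tuning knobs of the fitting pipeline.

    ``aic_penalty`` selects the parameter count entering AIC: ``"effective"``
    uses (J+2)K+1 (the method's conventional count), ``"full"`` uses the
    dimension of the free parameter vector, (2J+1)K+1.  The two agree for
    univariate data.  ``power_definition`` controls how an oscillator's power
    is measured when ranking: ``"latent"`` is the stationary variance
    sigma2/(1-a^2) of the latent coordinate, ``"observed"`` multiplies by the
    squared projection norm onto the reference series (always 1) and is kept
    for symmetry with per-series component variances.
    """

    kmax: int = 8
    n_starts: int = 3
    aic_penalty: str = "effective"
    maxiter: int = 500
    a_max: float = 1.0 - 1e-6
    power_definition: str = "latent"
    warm_start: bool = False

    def __post_init__(self) -> None:
        if self.aic_penalty not in ("effective", "full"):
            raise ValueError("aic_penalty must be 'effective' or 'full'")
        if self.power_definition not in ("latent", "observed"):
            raise ValueError("power_definition must be 'latent' or 'observed'")


def penalty_count(K: int, J: int, rule: str = "effective") -> int:
    """Number of parameters entering the AIC penalty 2*count."""
    if rule == "effective":
        return (J + 2) * K + 1
    return (2 * J + 1) * K + 1


@dataclass
class FitResult:
    """MLE of the K-oscillator model with its likelihood and AIC."""

    model: OscModel
    total_loglik: float
    loglik_per_time: np.ndarray
    aic: float
    converged: bool
    n_evals: int
    _fisher: np.ndarray | None = field(default=None, repr=False)

    @property
    def K(self) -> int:
        return self.model.K


@dataclass
class DecompResult:
    """Full decomposition: per-K fits, selected model and smoothed components.

    ``components[j, k]`` is the projection of the smoothed trajectory of
    oscillator k onto series j (length N); adding the residual reproduces the
    data exactly.  ``phases[k]`` is arg(x1 + i*x2) of the smoothed oscillator
    coordinates, in degrees [0, 360).
    """

    data: TimeSeriesData
    fits: tuple
    best_K: int
    trajectory: StateTrajectory
    components: np.ndarray
    component_sd: np.ndarray
    phases: np.ndarray

    @property
    def best(self) -> FitResult:
        for fr in self.fits:
            if fr.K == self.best_K:
                return fr
        raise RuntimeError("no fit for selected K")  # pragma: no cover

    @property
    def aic_trace(self) -> dict:
        return {fr.K: fr.aic for fr in self.fits}

    def residual(self, j: int) -> np.ndarray:
        return self.data.values[:, j] - self.components[j].sum(axis=0)


@dataclass
class PhaseDifferenceEstimate:
    """Delta-method estimate of a projection phase delay with its 95% CI."""

    oscillator: int
    series: int
    estimate_deg: float
    sd_deg: float
    ci95: tuple
    norm: float
    norm_sd: float


def oscillator_power(params: OscillatorParams) -> float:
    """Stationary variance sigma2/(1-a^2) of a latent oscillator coordinate."""
    return params.sigma2 / (1.0 - params.a**2)


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------


def _pack(model: OscModel, config: FitConfig) -> np.ndarray:
    a = np.clip(model.a, _A_LO * 2, config.a_max * (1 - 1e-12))
    nyq = 0.5 / model.dt
    f = np.clip(model.f, nyq * 1e-8, nyq * (1 - 1e-12))
    s2 = np.maximum(model.sigma2, 1e-14)
    z = [
        logit((a - _A_LO) / (config.a_max - _A_LO)),
        logit(f / nyq),
        np.log(s2),
        model.projections[1:].ravel(),
        [np.log(max(model.tau2, 1e-14))],
    ]
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in z])


def _unpack(z: np.ndarray, K: int, J: int, dt: float, config: FitConfig):
    nyq = 0.5 / dt
    a = _A_LO + (config.a_max - _A_LO) * expit(z[:K])
    f = nyq * expit(z[K : 2 * K])
    s2 = np.exp(z[2 * K : 3 * K])
    c_rest = z[3 * K : 3 * K + 2 * K * (J - 1)].reshape(J - 1, K, 2)
    tau2 = math.exp(z[-1])
    return a, f, s2, c_rest, tau2


def _unpack_model(z: np.ndarray, K: int, J: int, dt: float, config: FitConfig) -> OscModel:
    a, f, s2, c_rest, tau2 = _unpack(z, K, J, dt, config)
    proj = np.concatenate([np.tile([1.0, 0.0], (1, K, 1)), c_rest], axis=0)
    oscs = tuple(OscillatorParams(a=ai, f=min(fi, 0.5 / dt), sigma2=s2i) for ai, fi, s2i in zip(a, f, s2))
    return OscModel(oscillators=oscs, projections=proj, tau2=tau2, dt=dt)


def _negloglik_z(z: np.ndarray, K: int, J: int, y: np.ndarray, dt: float, config: FitConfig) -> float:
    a, f, s2, c_rest, tau2 = _unpack(z, K, J, dt, config)
    theta = 2.0 * np.pi * f * dt
    H = np.zeros((J, 2 * K))
    H[0, 0::2] = 1.0
    for j in range(1, J):
        H[j, 0::2] = c_rest[j - 1, :, 0]
        H[j, 1::2] = c_rest[j - 1, :, 1]
    P0 = np.zeros((2 * K, 2 * K))
    pw = s2 / (1.0 - a**2)
    P0[np.arange(2 * K), np.arange(2 * K)] = np.repeat(pw, 2)
    ll = filter_loglik(np.cos(theta), np.sin(theta), a, s2, H, tau2, y, P0)
    total = float(np.sum(ll))
    if not np.isfinite(total):
        return 1e12
    return -total


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _ar_roots(y: np.ndarray, order: int) -> np.ndarray:
    """Roots of the Yule-Walker AR(order) characteristic polynomial."""
    y = y - y.mean()
    n = y.size
    acov = np.array([np.dot(y[: n - lag], y[lag:]) / n for lag in range(order + 1)])
    if acov[0] <= 0:
        raise ValueError("zero-variance series")
    phi = solve_toeplitz(acov[:order], acov[1 : order + 1])
    return np.roots(np.concatenate([[1.0], -phi]))


def initialize_params(data: TimeSeriesData, K: int, config: FitConfig | None = None) -> OscModel:
    """Deterministic initial guess from AR roots of the reference series.

    Complex root pairs of an AR(2K) fit supply (a, f) via modulus and
    argument; if fewer than K conjugate pairs exist the remaining frequencies
    are equispaced on (0, Nyquist).  Innovation variances partition the
    reference-series variance equally; projections start in phase with
    amplitude given by regression of each series on the reference.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    config = config or FitConfig()
    y1 = data.values[:, 0]
    nyq = data.nyquist
    pairs: list[tuple[float, float]] = []
    try:
        roots = _ar_roots(y1, 2 * K)
        # complex-conjugate pairs carry (a, f); positive real roots are slow
        # components whose tiny rotation angle collapses to zero in the AR fit
        cand = list(roots[np.imag(roots) > 1e-10])
        cand += list(roots[(np.abs(np.imag(roots)) <= 1e-10) & (np.real(roots) > 0.2)])
        cand.sort(key=lambda r: -abs(r))
        for r in cand[:K]:
            a = float(np.clip(np.abs(r), 0.05, config.a_max))
            f = float(np.clip(np.angle(r) / (2.0 * np.pi * data.dt), nyq * 2e-3, nyq * 0.999))
            pairs.append((a, f))
    except (ValueError, np.linalg.LinAlgError):
        pass
    missing = K - len(pairs)
    if missing > 0:
        fill = nyq * (np.arange(1, missing + 1)) / (missing + 1)
        pairs.extend((0.9, float(fv)) for fv in fill)
    pairs.sort(key=lambda p: p[1])
    var1 = float(np.var(y1))
    if var1 <= 0:
        var1 = 1.0
    oscs = tuple(
        OscillatorParams(a=a, f=f, sigma2=max(0.9 * var1 / K * (1.0 - a**2), 1e-12))
        for a, f in pairs
    )
    J = data.n_series
    proj = np.zeros((J, K, 2))
    proj[0, :, 0] = 1.0
    for j in range(1, J):
        beta = float(np.cov(data.values[:, j], y1)[0, 1] / var1)
        proj[j, :, 0] = beta if abs(beta) > 1e-3 else 0.5
    return OscModel(oscillators=oscs, projections=proj, tau2=max(0.01 * var1, 1e-10), dt=data.dt)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _sorted_by_frequency(model: OscModel) -> OscModel:
    order = np.argsort([o.f for o in model.oscillators], kind="stable")
    return model.reordered(order)


def _augmented_model(prev: OscModel, data: TimeSeriesData) -> OscModel:
    """Warm start for K+1 oscillators: the previous MLE plus one oscillator
    seeded at the dominant residual frequency (Welch periodogram of the
    reference-series residual after removing the smoothed components)."""
    from scipy.signal import welch

    traj = kalman_smoother(prev, data)
    resid = data.values[:, 0] - traj.means[:, 0::2].sum(axis=1)
    nper = min(512, data.n_samples)
    freqs, pxx = welch(resid, fs=1.0 / data.dt, nperseg=nper, detrend=False)
    nyq = data.nyquist
    f_new = float(np.clip(freqs[1 + np.argmax(pxx[1:])], nyq * 2e-3, nyq * 0.999))
    a_new = 0.9
    rvar = max(float(np.var(resid)), 1e-12)
    new_osc = OscillatorParams(a=a_new, f=f_new, sigma2=0.5 * rvar * (1.0 - a_new**2))
    proj = np.concatenate([prev.projections, np.zeros((prev.J, 1, 2))], axis=1)
    proj[0, -1] = (1.0, 0.0)
    x1, x2 = traj.means[:, 0::2], traj.means[:, 1::2]
    for j in range(1, prev.J):
        recon_j = x1 @ prev.projections[j, :, 0] + x2 @ prev.projections[j, :, 1]
        rj = data.values[:, j] - recon_j
        beta = float(np.cov(rj, resid)[0, 1] / rvar)
        proj[j, -1] = (beta, 0.0)
    return OscModel(
        oscillators=prev.oscillators + (new_osc,),
        projections=proj,
        tau2=prev.tau2,
        dt=prev.dt,
    )


def fit_single_k(
    data: TimeSeriesData,
    K: int,
    config: FitConfig | None = None,
    warm: OscModel | None = None,
) -> FitResult:
    """MLE of the K-oscillator model by multi-start quasi-Newton.

    Starts from the AR-root initialization plus ``n_starts - 1`` jittered
    copies (deterministic jitter); a warm-start model (e.g. the previous K's
    optimum augmented by one oscillator) replaces the plain AR start when
    supplied.  The best achieved likelihood wins.  Oscillators in the
    returned model are sorted by frequency.
    """
    config = config or FitConfig()
    J = data.n_series
    y = data.values
    z_ar = _pack(initialize_params(data, K, config), config)
    starts = [z_ar]
    if warm is not None:
        starts.append(_pack(warm, config))
    for extra in range(1, config.n_starts):
        rng = np.random.default_rng(90_000 + 257 * K + extra)
        z = z_ar.copy()
        z[: 3 * K] = z[: 3 * K] + rng.normal(scale=0.4, size=3 * K)
        z[K : 2 * K] = z[K : 2 * K] + rng.normal(scale=0.6, size=K)
        starts.append(z)
    best = None
    n_evals = 0
    for z in starts:
        res = minimize(
            _negloglik_z,
            z,
            args=(K, J, y, data.dt, config),
            method="L-BFGS-B",
            options={"maxiter": config.maxiter, "maxfun": 10 * config.maxiter * (z.size + 1)},
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    model = _sorted_by_frequency(_unpack_model(best.x, K, J, data.dt, config))
    ll = loglik_per_time(model, data)
    total = float(np.sum(ll))
    aic = -2.0 * total + 2.0 * penalty_count(K, J, config.aic_penalty)
    return FitResult(
        model=model,
        total_loglik=total,
        loglik_per_time=ll,
        aic=aic,
        converged=bool(best.success),
        n_evals=n_evals,
    )


def _decompose(data: TimeSeriesData, fit: FitResult) -> tuple[StateTrajectory, np.ndarray, np.ndarray, np.ndarray]:
    traj = kalman_smoother(fit.model, data)
    N = data.n_samples
    J, K = fit.model.J, fit.model.K
    comps = np.zeros((J, K, N))
    sds = np.zeros((J, K, N))
    for k in range(K):
        xk = traj.means[:, 2 * k : 2 * k + 2]
        Pk = traj.covariances[:, 2 * k : 2 * k + 2, 2 * k : 2 * k + 2]
        for j in range(J):
            c = fit.model.projections[j, k]
            comps[j, k] = xk @ c
            sds[j, k] = np.sqrt(np.maximum(np.einsum("i,tij,j->t", c, Pk, c), 0.0))
    phases = np.degrees(np.arctan2(traj.means[:, 1::2], traj.means[:, 0::2])).T % 360.0
    return traj, comps, sds, phases


def fit_oscillators(
    data: TimeSeriesData,
    kmax: int | None = None,
    config: FitConfig | None = None,
    ks: list[int] | None = None,
) -> DecompResult:
    """Fit models for K = 1..kmax, select K by AIC and decompose the data.

    ``ks`` may restrict the candidate set (e.g. a single fixed K).  Ties in
    AIC break toward the smaller K.  Raises if every candidate fit fails.
    """
    config = config or FitConfig()
    if ks is None:
        kmax = kmax if kmax is not None else config.kmax
        if kmax < 1:
            raise ValueError("kmax must be at least 1")
        ks = list(range(1, kmax + 1))
    fits = []
    errors = []
    prev: FitResult | None = None
    for K in ks:
        warm = None
        if config.warm_start and prev is not None and K == prev.K + 1:
            try:
                warm = _augmented_model(prev.model, data)
            except (ValueError, np.linalg.LinAlgError):  # pragma: no cover - defensive
                warm = None
        try:
            fr = fit_single_k(data, K, config, warm=warm)
            fits.append(fr)
            prev = fr
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            errors.append((K, exc))
            warnings.warn(f"fit failed for K={K}: {exc}")
    if not fits:
        raise RuntimeError(f"all fits failed: {errors}")
    best_fit = min(fits, key=lambda fr: (fr.aic, fr.K))
    traj, comps, sds, phases = _decompose(data, best_fit)
    return DecompResult(
        data=data,
        fits=tuple(fits),
        best_K=best_fit.K,
        trajectory=traj,
        components=comps,
        component_sd=sds,
        phases=phases,
    )


# ---------------------------------------------------------------------------
# observed information and phase-difference confidence intervals
# ---------------------------------------------------------------------------


def _pack_natural(model: OscModel) -> np.ndarray:
    return np.concatenate([model.a, model.f, model.sigma2, model.projections[1:].ravel(), [model.tau2]])


def _negloglik_natural(x: np.ndarray, K: int, J: int, y: np.ndarray, dt: float) -> float:
    a = x[:K]
    f = x[K : 2 * K]
    s2 = x[2 * K : 3 * K]
    c_rest = x[3 * K : 3 * K + 2 * K * (J - 1)].reshape(J - 1, K, 2)
    tau2 = x[-1]
    if np.any(a <= 0) or np.any(a >= 1) or np.any(s2 < 0) or tau2 <= 0:
        return 1e12
    theta = 2.0 * np.pi * f * dt
    H = np.zeros((J, 2 * K))
    H[0, 0::2] = 1.0
    for j in range(1, J):
        H[j, 0::2] = c_rest[j - 1, :, 0]
        H[j, 1::2] = c_rest[j - 1, :, 1]
    P0 = np.zeros((2 * K, 2 * K))
    P0[np.arange(2 * K), np.arange(2 * K)] = np.repeat(s2 / (1.0 - a**2), 2)
    ll = filter_loglik(np.cos(theta), np.sin(theta), a, s2, H, tau2, y, P0)
    total = float(np.sum(ll))
    return 1e12 if not np.isfinite(total) else -total


def observed_information(model: OscModel, data: TimeSeriesData, step_scale: float = 1e-4) -> np.ndarray:
    """Observed Fisher information: finite-difference Hessian of the negative
    log marginal likelihood at the given (maximum likelihood) parameters.

    Parameter order: a_1..a_K, f_1..f_K, sigma2_1..sigma2_K, projection
    entries of series 2..J (row-major over (series, oscillator, component)),
    tau2.  Central differences with per-parameter scaled steps.
    """
    K, J = model.K, model.J
    x0 = _pack_natural(model)
    y = data.values
    p = x0.size
    h = step_scale * np.maximum(np.abs(x0), 1e-2)
    h[:K] = np.minimum(h[:K], (1.0 - x0[:K]) / 4.0)  # keep a < 1

    def fun(x):
        return _negloglik_natural(x, K, J, y, model.dt)

    f0 = fun(x0)
    hess = np.zeros((p, p))
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        xp = x0.copy()
        xm = x0.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp[i] = fun(xp)
        fm[i] = fun(xm)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp = x0.copy()
            xpm = x0.copy()
            xmp = x0.copy()
            xmm = x0.copy()
            xpp[i] += h[i]
            xpp[j] += h[j]
            xpm[i] += h[i]
            xpm[j] -= h[j]
            xmp[i] -= h[i]
            xmp[j] += h[j]
            xmm[i] -= h[i]
            xmm[j] -= h[j]
            hess[i, j] = hess[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4.0 * h[i] * h[j])
    return hess


def phase_difference_ci(
    fit: FitResult,
    data: TimeSeriesData,
    j: int = 1,
    k: int = 0,
    step_scale: float = 1e-4,
) -> PhaseDifferenceEstimate:
    """Phase delay of oscillator ``k`` on series ``j`` with delta-method 95% CI.

    The covariance of the projection entries (c1, c2) is the corresponding
    block of the inverse observed information; the phase variance follows
    from the gradient (-c2, c1)/(c1^2+c2^2).  ``j`` is a 0-based series index
    and must be >= 1 (series 0 is the phase reference).  The CI endpoints are
    reported un-wrapped around the estimate.
    """
    model = fit.model
    if not 1 <= j < model.J:
        raise ValueError("series index must be >= 1 (series 0 is the reference)")
    if not 0 <= k < model.K:
        raise ValueError(f"oscillator index out of range: {k}")
    c1, c2 = model.projections[j, k]
    r2 = c1 * c1 + c2 * c2
    if r2 == 0.0:
        raise ValueError("projection vector is zero: phase undefined")
    if fit._fisher is None:
        fit._fisher = observed_information(model, data, step_scale=step_scale)
    info = fit._fisher
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "observed information is singular; inspect optimizer convergence"
        ) from exc
    K = model.K
    idx = 3 * K + 2 * ((j - 1) * K + k)
    block = cov[np.ix_([idx, idx + 1], [idx, idx + 1])]
    if not np.all(np.isfinite(block)):
        raise np.linalg.LinAlgError(
            "non-finite projection covariance; inspect optimizer convergence"
        )
    g_phase = np.array([-c2, c1]) / r2
    var_phase = float(g_phase @ block @ g_phase)
    norm = math.sqrt(r2)
    g_norm = np.array([c1, c2]) / norm
    var_norm = float(g_norm @ block @ g_norm)
    if var_phase < 0 or var_norm < 0:
        raise np.linalg.LinAlgError(
            "negative delta-method variance; observed information is not positive "
            "definite at the reported optimum - inspect convergence"
        )
    est = math.degrees(math.atan2(c2, c1)) % 360.0
    sd = math.degrees(math.sqrt(var_phase))
    return PhaseDifferenceEstimate(
        oscillator=k,
        series=j,
        estimate_deg=est,
        sd_deg=sd,
        ci95=(est - 1.96 * sd, est + 1.96 * sd),
        norm=norm,
        norm_sd=math.sqrt(var_norm),
    )
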