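"""Oscillator state-space model: containers, exact Gaussian inference, simulation.

The model represents a J-dimensional time series ``y`` as the superposition of
K latent stochastic oscillators.  Oscillator k is a point in the plane that
rotates about the origin by an angle ``2*pi*f_k*dt`` per step, is damped by a
regularity factor ``a_k`` in (0, 1) and receives isotropic Gaussian innovations
with variance ``sigma2_k``::

    x_{t+1}^{(k)} = a_k * R(2*pi*f_k*dt) x_t^{(k)} + v_t^{(k)},
    v_t^{(k)} ~ N(0, sigma2_k * I_2)

    y_{t,j} = sum_k ( c_{jk,1} x_{t,1}^{(k)} + c_{jk,2} x_{t,2}^{(k)} ) + w_{t,j},
    w_{t,j} ~ N(0, tau2)

The projection vector (c_{jk,1}, c_{jk,2}) superposes oscillator k on series j
with amplitude ``|c|`` and phase delay ``arg(c1 + i c2)``.  For identifiability
the projection onto the first (reference) series is fixed at (1, 0).

Everything here is exact for the Gaussian linear model: the Kalman filter
yields the marginal likelihood by prediction-error decomposition, and the
Rauch-Tung-Striebel smoother yields the posterior of every oscillator
coordinate given all the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kalman import filter_loglik

__all__ = [
    "TimeSeriesData",
    "OscillatorParams",
    "OscModel",
    "StateTrajectory",
    "KalmanResult",
    "build_model",
    "stationary_state_cov",
    "kalman_filter",
    "kalman_smoother",
    "log_likelihood",
    "loglik_per_time",
    "simulate_ssm",
    "simulate_states",
    "component_spectrum",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesData:
    """An N x J observed multivariate time series with uniform sampling.

    Parameters
    ----------
    values : ndarray, shape (N, J)
        Observed series in columns (mM.mm for fNIRS oxy/deoxy pairs).
    dt : float
        Sampling period in seconds.
    series_labels : sequence of str, optional
        One label per column, e.g. ``("oxy", "deoxy")``.
    channel_id : str, optional
        Measurement-channel identifier (e.g. ``"L3"``).
    """

    values: np.ndarray
    dt: float
    series_labels: tuple = ()
    channel_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be an N x J matrix")
        n, j = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if j < 1:
            raise ValueError("need at least one series")
        if self.dt <= 0:
            raise ValueError(f"sampling period must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            t, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at row {t}, series {s} (missing data is rejected)")
        if self.series_labels:
            self.series_labels = tuple(self.series_labels)
            if len(self.series_labels) != j:
                raise ValueError("series_labels length must match number of columns")
        else:
            self.series_labels = tuple(f"series{i + 1}" for i in range(j))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_series(self) -> int:
        return self.values.shape[1]

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.dt

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of one latent oscillator.

    ``a`` is the regularity (damping) in (0, 1): the closer to one, the more
    sinusoidal the waveform and the narrower the spectral peak.  ``f`` is the
    rotation frequency in Hz.  ``sigma2`` is the innovation variance; the
    stationary variance of each coordinate is ``sigma2 / (1 - a**2)``, which
    is the oscillator's power.
    """

    a: float
    f: float
    sigma2: float

    def __post_init__(self) -> None:
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"regularity a must lie in (0, 1), got {self.a}")
        if self.f < 0.0:
            raise ValueError(f"frequency must be nonnegative, got {self.f}")
        if self.sigma2 < 0.0:
            raise ValueError(f"innovation variance must be nonnegative, got {self.sigma2}")

    @property
    def power(self) -> float:
        """Stationary variance sigma2 / (1 - a^2) of each coordinate."""
        return self.sigma2 / (1.0 - self.a**2)


@dataclass
class OscModel:
    """A K-oscillator state-space model for a J-dimensional series.

    ``projections`` is a (J, K, 2) array of projection vectors; row 0 (the
    reference series) is fixed at (1, 0) for every oscillator.
    """

    oscillators: tuple
    projections: np.ndarray
    tau2: float
    dt: float

    def __post_init__(self) -> None:
        self.oscillators = tuple(self.oscillators)
        if not self.oscillators:
            raise ValueError("need at least one oscillator")
        self.projections = np.asarray(self.projections, dtype=float)
        if self.projections.ndim != 3 or self.projections.shape[1] != len(self.oscillators) or self.projections.shape[2] != 2:
            raise ValueError("projections must have shape (J, K, 2)")
        if self.tau2 <= 0:
            raise ValueError(f"observation-noise variance must be positive, got {self.tau2}")
        if self.dt <= 0:
            raise ValueError("sampling period must be positive")
        if not np.allclose(self.projections[0], [1.0, 0.0]):
            raise ValueError("reference-series projections must be fixed at (1, 0)")
        nyq = 0.5 / self.dt
        for k, osc in enumerate(self.oscillators):
            if osc.f > nyq * (1 + 1e-12):
                raise ValueError(f"oscillator {k}: frequency {osc.f} Hz exceeds Nyquist {nyq} Hz")

    @property
    def K(self) -> int:
        return len(self.oscillators)

    @property
    def J(self) -> int:
        return self.projections.shape[0]

    @property
    def a(self) -> np.ndarray:
        return np.array([o.a for o in self.oscillators])

    @property
    def f(self) -> np.ndarray:
        return np.array([o.f for o in self.oscillators])

    @property
    def sigma2(self) -> np.ndarray:
        return np.array([o.sigma2 for o in self.oscillators])

    def phase_delay_deg(self, j: int, k: int) -> float:
        """Phase delay arg(c_{jk,1} + i c_{jk,2}) of oscillator k on series j, degrees in [0, 360)."""
        c1, c2 = self.projections[j, k]
        return float(np.degrees(np.arctan2(c2, c1)) % 360.0)

    def projection_norm(self, j: int, k: int) -> float:
        return float(np.hypot(*self.projections[j, k]))

    def reordered(self, order: Sequence[int]) -> "OscModel":
        """Model with oscillators permuted (projections follow)."""
        order = list(order)
        return OscModel(
            oscillators=tuple(self.oscillators[k] for k in order),
            projections=self.projections[:, order, :],
            tau2=self.tau2,
            dt=self.dt,
        )


@dataclass
class KalmanResult:
    """Forward-pass output: predicted/filtered moments and per-time log densities."""

    loglik_per_time: np.ndarray
    filtered_means: np.ndarray
    filtered_covs: np.ndarray
    predicted_means: np.ndarray
    predicted_covs: np.ndarray

    @property
    def total_loglik(self) -> float:
        return float(np.sum(self.loglik_per_time))


@dataclass
class StateTrajectory:
    """Posterior (smoothed) moments of all 2K oscillator coordinates.

    ``means[t]`` and ``covariances[t]`` are the posterior mean and covariance
    of (x_{t,1}^{(1)}, x_{t,2}^{(1)}, ..., x_{t,2}^{(K)}) given y_1..y_N.
    A 95% credible interval for any coordinate is mean +/- 1.96 posterior sd.
    """

    means: np.ndarray
    covariances: np.ndarray
    loglik_per_time: np.ndarray = field(default=None, repr=False)

    @property
    def total_loglik(self) -> float:
        return float(np.sum(self.loglik_per_time))


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


def rotation(theta: float) -> np.ndarray:
    """Counter-clockwise 2x2 rotation matrix."""
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def build_model(model: OscModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (F, Q, H, R) state-space matrices.

    F is 2K x 2K block-diagonal with k-th block ``a_k * R(2*pi*f_k*dt)``;
    Q is block-diagonal ``sigma2_k * I_2``; H stacks the projection vectors;
    R = tau2 * I_J.
    """
    K, J = model.K, model.J
    F = np.zeros((2 * K, 2 * K))
    Q = np.zeros((2 * K, 2 * K))
    H = np.zeros((J, 2 * K))
    for k, osc in enumerate(model.oscillators):
        theta = 2.0 * math.pi * osc.f * model.dt
        F[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = osc.a * rotation(theta)
        Q[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = osc.sigma2 * np.eye(2)
        H[:, 2 * k : 2 * k + 2] = model.projections[:, k, :]
    R = model.tau2 * np.eye(J)
    return F, Q, H, R


def stationary_state_cov(model: OscModel) -> np.ndarray:
    """Stationary state covariance: block-diagonal sigma2_k/(1-a_k^2) * I_2."""
    K = model.K
    P0 = np.zeros((2 * K, 2 * K))
    for k, osc in enumerate(model.oscillators):
        P0[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = osc.power * np.eye(2)
    return P0


def _kernel_args(model: OscModel, data: TimeSeriesData):
    if data.n_series != model.J:
        raise ValueError(f"data has {data.n_series} series but model expects {model.J}")
    if abs(data.dt - model.dt) > 1e-12 * max(1.0, model.dt):
        raise ValueError("data and model sampling periods differ")
    theta = 2.0 * np.pi * model.f * model.dt
    _, _, H, _ = build_model(model)
    return (
        np.cos(theta),
        np.sin(theta),
        model.a,
        model.sigma2,
        H,
        model.tau2,
        data.values,
        stationary_state_cov(model),
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def loglik_per_time(model: OscModel, data: TimeSeriesData) -> np.ndarray:
    """Per-time log predictive densities l_t = log p(y_t | y_1..y_{t-1}).

    l_1 is the log density of y_1 under the stationary distribution of the
    model.  The sum of l_t is the exact log marginal likelihood.
    """
    ll = filter_loglik(*_kernel_args(model, data))
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError(
            "innovation covariance became numerically singular during filtering; "
            "check model parameters (tau2, sigma2) and data scale"
        )
    return ll


def log_likelihood(model: OscModel, data: TimeSeriesData) -> float:
    """Exact log marginal likelihood of the data under the model."""
    return float(np.sum(loglik_per_time(model, data)))


def kalman_filter(model: OscModel, data: TimeSeriesData) -> KalmanResult:
    """Kalman filter with stationary initialization, storing all moments.

    Plain-NumPy reference implementation (the compiled kernel used during
    fitting computes the same recursion without storage); covariance updates
    use the Joseph form and are symmetrized each step.
    """
    F, Q, H, R = build_model(model)
    y = data.values
    N, J = y.shape
    n = F.shape[0]
    xp = np.zeros((N, n))
    Pp = np.zeros((N, n, n))
    xf = np.zeros((N, n))
    Pf = np.zeros((N, n, n))
    ll = np.zeros(N)
    x = np.zeros(n)
    P = stationary_state_cov(model)
    I_n = np.eye(n)
    for t in range(N):
        xp[t] = x
        Pp[t] = P
        v = y[t] - H @ x
        S = H @ P @ H.T + R
        try:
            Si = np.linalg.inv(S)
            sign, logdet = np.linalg.slogdet(S)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise FloatingPointError(f"singular innovation covariance at t={t}") from exc
        if sign <= 0:
            raise FloatingPointError(f"non-positive innovation covariance at t={t}")
        ll[t] = -0.5 * (J * np.log(2 * np.pi) + logdet + v @ Si @ v)
        G = P @ H.T @ Si
        x = x + G @ v
        IGH = I_n - G @ H
        P = IGH @ P @ IGH.T + G @ R @ G.T
        P = 0.5 * (P + P.T)
        xf[t] = x
        Pf[t] = P
        x = F @ x
        P = F @ P @ F.T + Q
        P = 0.5 * (P + P.T)
    return KalmanResult(ll, xf, Pf, xp, Pp)


def kalman_smoother(model: OscModel, data: TimeSeriesData) -> StateTrajectory:
    """Rauch-Tung-Striebel smoother: posterior moments given y_1..y_N."""
    F, _, _, _ = build_model(model)
    fr = kalman_filter(model, data)
    N, n = fr.filtered_means.shape
    xs = np.zeros((N, n))
    Ps = np.zeros((N, n, n))
    xs[-1] = fr.filtered_means[-1]
    Ps[-1] = fr.filtered_covs[-1]
    for t in range(N - 2, -1, -1):
        Pp_next = fr.predicted_covs[t + 1]
        G = fr.filtered_covs[t] @ F.T @ np.linalg.pinv(Pp_next)
        xs[t] = fr.filtered_means[t] + G @ (xs[t + 1] - fr.predicted_means[t + 1])
        Ps[t] = fr.filtered_covs[t] + G @ (Ps[t + 1] - Pp_next) @ G.T
        Ps[t] = 0.5 * (Ps[t] + Ps[t].T)
    return StateTrajectory(means=xs, covariances=Ps, loglik_per_time=fr.loglik_per_time)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_states(model: OscModel, n_samples: int, seed) -> np.ndarray:
    """Latent trajectories (N, 2K) drawn from the oscillator dynamics.

    The initial state is drawn from the stationary distribution.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = _as_rng(seed)
    K = model.K
    x = np.zeros((n_samples, 2 * K))
    for k, osc in enumerate(model.oscillators):
        A = osc.a * rotation(2.0 * math.pi * osc.f * model.dt)
        sd = math.sqrt(osc.sigma2)
        s = rng.normal(scale=math.sqrt(osc.power), size=2)
        x[0, 2 * k : 2 * k + 2] = s
        innov = rng.normal(scale=sd, size=(n_samples - 1, 2))
        for t in range(1, n_samples):
            s = A @ s + innov[t - 1]
            x[t, 2 * k : 2 * k + 2] = s
    return x


def simulate_ssm(model: OscModel, n_samples: int, seed) -> tuple[TimeSeriesData, np.ndarray]:
    """Simulate observations and latent states from the model.

    Returns the observed series and the (N, 2K) latent trajectory so that
    reconstruction error against the truth is computable.
    """
    rng = _as_rng(seed)
    x = simulate_states(model, n_samples, rng)
    _, _, H, _ = build_model(model)
    y = x @ H.T + rng.normal(scale=math.sqrt(model.tau2), size=(n_samples, model.J))
    labels = ("oxy", "deoxy") if model.J == 2 else ()
    return TimeSeriesData(values=y, dt=model.dt, series_labels=labels), x


# ---------------------------------------------------------------------------
# theoretical spectra
# ---------------------------------------------------------------------------


def component_spectrum(model: OscModel, freqs: np.ndarray) -> dict:
    """Theoretical spectral densities of each oscillation component.

    For oscillator k and series j the density at frequency f (Hz) is computed
    from the state-space transfer form ``c^T (e^{iw} I - F_k)^-1 Q_k
    (e^{-iw} I - F_k^T)^-1 c`` with ``w = 2*pi*f*dt``; each observed
    component of oscillator k is an ARMA(2,1) process and this is its exact
    spectrum.  Densities are per Hz, normalized so that the integral over
    [-Nyquist, Nyquist] equals the stationary variance of the component;
    the observation noise contributes a flat floor ``tau2 * dt``.

    Returns a dict with ``freqs``, ``per_oscillator`` (J, K, nf), ``noise``
    (scalar) and ``total`` (J, nf) arrays.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    nyq = 0.5 / model.dt
    if np.any(freqs < -nyq - 1e-12) or np.any(freqs > nyq + 1e-12):
        raise ValueError("frequency grid must lie within [-Nyquist, Nyquist]")
    J, K = model.J, model.K
    out = np.zeros((J, K, freqs.size))
    I2 = np.eye(2)
    for k, osc in enumerate(model.oscillators):
        A = osc.a * rotation(2.0 * math.pi * osc.f * model.dt)
        for i, f in enumerate(freqs):
            z = np.exp(1j * 2.0 * math.pi * f * model.dt)
            M = np.linalg.inv(z * I2 - A)
            Sx = osc.sigma2 * (M @ M.conj().T)
            for j in range(J):
                c = model.projections[j, k]
                out[j, k, i] = float(np.real(c @ Sx @ c)) * model.dt
    noise_floor = model.tau2 * model.dt
    total = out.sum(axis=1) + noise_floor
    return {"freqs": freqs, "per_oscillator": out, "noise": noise_floor, "total": total}
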