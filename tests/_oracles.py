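"""Independent brute-force oracles for exact Gaussian inference.

Everything here works from the explicitly assembled joint Gaussian
distribution of states and observations and never touches the package's
recursive filter/smoother implementations.
"""

from __future__ import annotations

import numpy as np

from oscdecomp.ssm_core import OscModel, TimeSeriesData, build_model, stationary_state_cov


def joint_state_obs_cov(model: OscModel, n: int):
    """Mean-zero joint covariance of (all states, all observations).

    States are stationary, so Cov(x_{t+h}, x_t) = F^h P0.  Returns
    (cov_xx, cov_yx, cov_yy) with states stacked time-major.
    """
    F, _, H, R = build_model(model)
    d = F.shape[0]
    P0 = stationary_state_cov(model)
    powers = [np.eye(d)]
    for _ in range(n):
        powers.append(powers[-1] @ F)
    cov_xx = np.zeros((n * d, n * d))
    for t in range(n):
        for s in range(n):
            blk = powers[t - s] @ P0 if t >= s else (powers[s - t] @ P0).T
            cov_xx[t * d : (t + 1) * d, s * d : (s + 1) * d] = blk
    Hbig = np.kron(np.eye(n), H)
    cov_yx = Hbig @ cov_xx
    cov_yy = cov_yx @ Hbig.T + np.kron(np.eye(n), R)
    return cov_xx, cov_yx, cov_yy


def brute_loglik(model: OscModel, data: TimeSeriesData) -> float:
    """Log density of the stacked observation vector under the joint Gaussian."""
    _, _, cov_yy = joint_state_obs_cov(model, data.n_samples)
    y = data.values.ravel()
    sign, logdet = np.linalg.slogdet(cov_yy)
    assert sign > 0
    return float(-0.5 * (y.size * np.log(2 * np.pi) + logdet + y @ np.linalg.solve(cov_yy, y)))


def brute_smoother(model: OscModel, data: TimeSeriesData):
    """Conditional mean and covariance of all states given all observations."""
    n = data.n_samples
    d = 2 * model.K
    cov_xx, cov_yx, cov_yy = joint_state_obs_cov(model, n)
    y = data.values.ravel()
    gain = np.linalg.solve(cov_yy, cov_yx).T
    mean = (gain @ y).reshape(n, d)
    cov_full = cov_xx - gain @ cov_yx
    covs = np.array([cov_full[t * d : (t + 1) * d, t * d : (t + 1) * d] for t in range(n)])
    return mean, covs


def random_model(rng: np.random.Generator, K: int, J: int, dt: float = 0.1) -> OscModel:
    """A random valid oscillator model with well-conditioned parameters."""
    from oscdecomp.ssm_core import OscillatorParams

    nyq = 0.5 / dt
    oscs = tuple(
        OscillatorParams(
            a=float(rng.uniform(0.3, 0.97)),
            f=float(rng.uniform(0.05, 0.95) * nyq),
            sigma2=float(rng.uniform(0.05, 0.5)),
        )
        for _ in range(K)
    )
    proj = rng.normal(size=(J, K, 2))
    proj[0, :, 0] = 1.0
    proj[0, :, 1] = 0.0
    return OscModel(oscillators=oscs, projections=proj, tau2=float(rng.uniform(0.02, 0.3)), dt=dt)
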